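"""Genetic-algorithm projection pursuit for indicator weighting.

The standardized sample matrix x (n cells x m indicators) is projected
onto a unit direction c, V_i = sum_j c_j x_ij, and the direction is chosen
to maximize the projection index

    Q(c) = S(c) * D(c)

where S(c) is the sample standard deviation of the projection (overall
spread, n-1 denominator) and D(c) is the within-window density

    D(c) = sum_i sum_j (R - r_ij) * 1{r_ij < R},   r_ij = |V_i - V_j|,

a literal double sum over all ordered pairs including i == j (each
diagonal term contributes R) with a strict step function.  A large Q wants
projections that are globally dispersed yet locally clumped.  The window
radius R defaults to 0.1 * S(c), recomputed per candidate direction.

Optimization uses a real-coded genetic algorithm on the unit sphere
(tournament selection, arithmetic crossover, Gaussian mutation, elitism,
renormalization after every variation).  The squared components of the
optimal direction are the indicator weights, u_j = c_j**2, summing to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .grid_model import SampleMatrix

_UNIT_TOL = 1e-6


class ConstraintError(ValueError):
    """Direction vector violates the unit-sphere constraint."""


@dataclass
class GAParams:
    """Genetic-algorithm settings; defaults follow the study configuration
    (population 400, crossover 0.8, mutation 0.3, 200 elites kept)."""

    population_size: int = 400
    crossover_prob: float = 0.8
    mutation_prob: float = 0.3
    elite_count: int = 200
    max_generations: int = 200
    stall_generations: int = 30
    seed: int = 0
    mutation_sigma: float = 0.1
    subsample_threshold: int = 5000
    subsample_size: int = 2000

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not 0 <= self.elite_count < self.population_size:
            raise ValueError("elite_count must be < population_size")


@dataclass
class ProjectionObjective:
    S: float
    D: float
    Q: float
    R: float


@dataclass
class ProjectionResult:
    direction: np.ndarray
    weights: np.ndarray
    best_Q: float
    trace: np.ndarray
    params: GAParams
    R_used: float
    indicator_ids: list[str] = field(default_factory=list)

    def weight_map(self) -> dict[str, float]:
        ids = self.indicator_ids or [f"c{j}" for j in range(len(self.weights))]
        return {i: float(w) for i, w in zip(ids, self.weights)}

    def to_dict(self) -> dict:
        return {
            "direction": [float(v) for v in self.direction],
            "weights": [float(v) for v in self.weights],
            "best_Q": float(self.best_Q),
            "trace": [float(v) for v in self.trace],
            "R_used": float(self.R_used),
            "indicator_ids": list(self.indicator_ids),
            "params": {
                "population_size": self.params.population_size,
                "crossover_prob": self.params.crossover_prob,
                "mutation_prob": self.params.mutation_prob,
                "elite_count": self.params.elite_count,
                "max_generations": self.params.max_generations,
                "stall_generations": self.params.stall_generations,
                "seed": self.params.seed,
            },
        }


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, SampleMatrix):
        return x.x
    return np.asarray(x, dtype=float)


def _check_unit(c: np.ndarray) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if abs(float(c @ c) - 1.0) > _UNIT_TOL:
        raise ConstraintError(f"direction not on unit sphere: |c|^2 = {c @ c:.6f}")
    return c


def project(x, c: Sequence[float]) -> np.ndarray:
    """One-dimensional projection V_i = sum_j c_j x_ij of the samples."""
    mat = _as_matrix(x)
    c = _check_unit(c)
    if mat.shape[1] != c.shape[0]:
        raise ValueError(f"direction length {c.shape[0]} != m = {mat.shape[1]}")
    return mat @ c


def _density(v: np.ndarray, R: float) -> float:
    """Literal double-sum density via a sorted prefix-sum identity.

    Equals sum over all ordered pairs (incl. i==j) of (R - r)*1{r < R}:
    n*R from the diagonal plus twice the strictly-within off-diagonal sum.
    """
    n = v.shape[0]
    if R <= 0:
        return 0.0
    s = np.sort(v)
    lo = np.searchsorted(s, s - R, side="right")  # first j with s_j > s_i - R
    idx = np.arange(n)
    cnt = idx - lo
    prefix = np.concatenate(([0.0], np.cumsum(s)))
    win_sum = prefix[idx] - prefix[lo]
    off = float(np.sum(cnt * (R - s) + win_sum))
    return n * R + 2.0 * off


def objective(x, c: Sequence[float], R: float | str = "auto") -> ProjectionObjective:
    """Projection index Q = S * D for one direction.

    ``R="auto"`` resolves to 0.1 * S(c).  Explicit non-positive R is a
    parameter error.
    """
    v = project(x, c)
    if v.shape[0] < 2:
        raise ValueError("need at least two samples")
    S = float(np.std(v, ddof=1))
    if R == "auto":
        Rval = 0.1 * S
    else:
        Rval = float(R)
        if Rval <= 0:
            raise ValueError("window radius R must be positive")
    D = _density(v, Rval)
    return ProjectionObjective(S=S, D=D, Q=S * D, R=Rval)


def weights_from_direction(c: Sequence[float]) -> np.ndarray:
    """Squared direction components; non-negative, sum to 1, sign-invariant."""
    c = _check_unit(c)
    u = c * c
    return u / u.sum()


def _eval_population(mat: np.ndarray, pop: np.ndarray, R) -> np.ndarray:
    V = mat @ pop.T  # n x P
    q = np.empty(pop.shape[0])
    for k in range(pop.shape[0]):
        v = V[:, k]
        S = float(np.std(v, ddof=1))
        Rk = 0.1 * S if R == "auto" else float(R)
        q[k] = S * _density(v, Rk)
    return q


def _renormalize(pop: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    norms = np.linalg.norm(pop, axis=1)
    dead = norms < 1e-12
    if dead.any():
        pop[dead] = rng.normal(size=(dead.sum(), pop.shape[1]))
        norms = np.linalg.norm(pop, axis=1)
    return pop / norms[:, None]


def optimize_direction(x, params: GAParams | None = None,
                       R: float | str = "auto",
                       indicator_ids: Sequence[str] | None = None) -> ProjectionResult:
    """Search the unit sphere for the direction maximizing Q(c).

    Elitism makes the best-Q trace non-decreasing; a fixed seed gives a
    bit-identical result.  For n above ``subsample_threshold`` the
    objective is evolved on a seeded random subsample and the final Q is
    recomputed on the full sample.
    """
    params = params or GAParams()
    mat = _as_matrix(x)
    if isinstance(x, SampleMatrix) and indicator_ids is None:
        indicator_ids = x.indicator_ids
    n, m = mat.shape
    if m < 2 or n < 2:
        raise ValueError("need n >= 2 samples and m >= 2 indicators")
    if np.allclose(mat.std(axis=0), 0):
        warnings.warn("degenerate sample matrix: all columns constant",
                      stacklevel=2)
    rng = np.random.default_rng(params.seed)

    fit_mat = mat
    if n > params.subsample_threshold:
        pick = rng.choice(n, size=params.subsample_size, replace=False)
        fit_mat = mat[np.sort(pick)]

    P, E = params.population_size, params.elite_count
    pop = _renormalize(rng.normal(size=(P, m)), rng)
    fitness = _eval_population(fit_mat, pop, R)

    trace = []
    best_q = -np.inf
    best_c = pop[0].copy()
    stall = 0
    for _gen in range(params.max_generations):
        order = np.argsort(fitness)[::-1]
        pop, fitness = pop[order], fitness[order]
        gen_best = float(fitness[0])
        if gen_best > best_q * (1 + 1e-8) + 1e-300:
            stall = 0
        else:
            stall += 1
        if gen_best > best_q:
            best_q, best_c = gen_best, pop[0].copy()
        trace.append(best_q)
        if stall >= params.stall_generations:
            break

        elites = pop[:E].copy()
        n_off = P - E
        # tournament selection, size 2
        cand = rng.integers(0, P, size=(2, 2 * n_off))
        winners = np.where(fitness[cand[0]] >= fitness[cand[1]], cand[0], cand[1])
        pa, pb = pop[winners[:n_off]], pop[winners[n_off:]]
        # arithmetic crossover
        do_x = rng.random(n_off) < params.crossover_prob
        alpha = rng.random((n_off, 1))
        children = np.where(do_x[:, None], alpha * pa + (1 - alpha) * pb, pa)
        # Gaussian mutation
        do_m = rng.random(n_off) < params.mutation_prob
        noise = rng.normal(scale=params.mutation_sigma, size=(n_off, m))
        children = children + do_m[:, None] * noise
        children = _renormalize(children, rng)
        child_fit = _eval_population(fit_mat, children, R)
        pop = np.vstack([elites, children])
        fitness = np.concatenate([fitness[:E], child_fit])

    final = objective(mat, best_c, R)
    return ProjectionResult(
        direction=best_c,
        weights=weights_from_direction(best_c),
        best_Q=final.Q,
        trace=np.asarray(trace),
        params=params,
        R_used=final.R,
        indicator_ids=list(indicator_ids or []),
    )


def sweep_2d(x, n_angles: int = 10000, R: float | str = "auto") -> ProjectionResult:
    """Brute-force angular sweep for m == 2; independent check on the GA."""
    mat = _as_matrix(x)
    if mat.shape[1] != 2:
        raise ValueError("angular sweep only defined for m == 2")
    thetas = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    best_q, best_c = -np.inf, None
    for t in thetas:
        c = np.array([np.cos(t), np.sin(t)])
        q = objective(mat, c, R).Q
        if q > best_q:
            best_q, best_c = q, c
    final = objective(mat, best_c, R)
    return ProjectionResult(best_c, weights_from_direction(best_c), final.Q,
                            np.array([final.Q]), GAParams(), final.R)
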