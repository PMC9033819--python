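"""Spatial autocorrelation of the quality surface.

The fine-resolution index is first aggregated to square analysis units
(the study uses 500 m meshes), a contiguity weight matrix is built on the
coarse lattice (queen by default, row-standardized), and global and local
Moran statistics are computed with permutation inference.

Global Moran's I uses the standard normalization

    I = (n / S0) * sum_ij w_ij d_i d_j / sum_i d_i**2,   d_i = x_i - mean,

with S0 the total weight; for row-standardized weights S0 = n.  The
literal textbook variant with the weight matrix folded into the
denominator is reported alongside as ``I_as_printed`` for transparency.
Local statistics follow

    I_i = n * d_i * sum_j w_ij d_j / sum_k d_k**2,

with conditional permutation (hold unit i, resample its neighbors from
the remaining units) pseudo p-values; significant units are labeled by
their Moran-scatter quadrant (H-H, L-L, H-L, L-H).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import sparse

from .grid_model import Grid


class ZeroVarianceError(ValueError):
    """Constant surface: Moran statistics undefined."""


@dataclass
class UnitLattice:
    """Coarse analysis units aggregated from the fine grid."""

    values: np.ndarray          # per retained unit
    positions: np.ndarray       # (n, 2) coarse (row, col)
    unit_size: float            # metres
    coverage: np.ndarray        # valid-cell fraction per retained unit
    lattice_shape: tuple[int, int] = (0, 0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SpatialWeights:
    neighbors: list[np.ndarray]       # neighbor indices per unit
    weights: list[np.ndarray]         # matching weights (w_ii = 0 implicit)
    scheme: str
    row_standardized: bool

    @property
    def n(self) -> int:
        return len(self.neighbors)

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbors, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))


@dataclass
class MoranResult:
    I: float
    expected_I: float
    z_score: float
    p_value: float
    n_perm: int
    seed: int
    I_as_printed: float = float("nan")
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")


@dataclass
class LisaResult:
    local_i: np.ndarray
    quadrant: np.ndarray          # "H-H" | "L-L" | "H-L" | "L-H"
    p_value: np.ndarray
    cluster_label: np.ndarray     # quadrant if significant else "not significant"
    alpha: float
    n_perm: int
    seed: int
    positions: np.ndarray | None = None


def resample_to_units(index: Grid, unit_size: float,
                      min_coverage: float = 0.5) -> UnitLattice:
    """Aggregate the index to square units by the mean of valid fine cells.

    ``unit_size`` must be a positive integer multiple of the cell size;
    units whose valid coverage falls below ``min_coverage`` are dropped.
    """
    f = unit_size / index.cell_size
    if f < 1 or abs(f - round(f)) > 1e-9:
        raise ValueError("unit_size must be a positive multiple of cell_size")
    f = int(round(f))
    nr, nc = index.shape
    ur, uc = -(-nr // f), -(-nc // f)
    vals = np.where(index.valid_mask, index.values, 0.0)
    ok = index.valid_mask.astype(float)
    pad_r, pad_c = ur * f - nr, uc * f - nc
    vals = np.pad(vals, ((0, pad_r), (0, pad_c)))
    ok = np.pad(ok, ((0, pad_r), (0, pad_c)))
    sums = vals.reshape(ur, f, uc, f).sum(axis=(1, 3))
    cnts = ok.reshape(ur, f, uc, f).sum(axis=(1, 3))
    coverage = cnts / (f * f)
    keep = coverage >= max(min_coverage, 1e-12)
    if not keep.any():
        raise ValueError("no unit retained; lower min_coverage")
    rr, cc = np.nonzero(keep)
    values = sums[rr, cc] / cnts[rr, cc]
    return UnitLattice(values=values, positions=np.column_stack([rr, cc]),
                       unit_size=float(unit_size), coverage=coverage[rr, cc],
                       lattice_shape=(ur, uc))


_QUEEN = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_ROOK = [(-1, 0), (0, -1), (0, 1), (1, 0)]


def build_weights(lattice: UnitLattice, scheme: str = "queen",
                  row_standardize: bool = True) -> SpatialWeights:
    """Contiguity weights on the coarse lattice (no self-neighbors)."""
    if lattice.n < 2:
        raise ValueError("need at least two units")
    offsets = {"queen": _QUEEN, "rook": _ROOK}[scheme]
    index = {(int(r), int(c)): i for i, (r, c) in enumerate(lattice.positions)}
    neighbors, weights = [], []
    for r, c in lattice.positions:
        nb = [index[(r + dr, c + dc)] for dr, dc in offsets
              if (r + dr, c + dc) in index]
        nb = np.array(sorted(nb), dtype=int)
        if row_standardize and len(nb):
            w = np.full(len(nb), 1.0 / len(nb))
        else:
            w = np.ones(len(nb))
        neighbors.append(nb)
        weights.append(w)
    return SpatialWeights(neighbors, weights, scheme, row_standardize)


def _deviations(y: np.ndarray) -> np.ndarray:
    d = y - y.mean()
    if np.allclose(d, 0):
        raise ZeroVarianceError("constant values: Moran's I undefined")
    return d


def _global_i(d: np.ndarray, W: sparse.csr_matrix, s0: float) -> float:
    n = d.shape[0]
    return float(n / s0 * (d @ (W @ d)) / (d @ d))


def global_moran(y: Sequence[float], W: SpatialWeights, n_perm: int = 999,
                 seed: int = 0) -> MoranResult:
    """Global Moran's I with permutation (relabeling) inference."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] < 2:
        raise ValueError("need at least 2 units")
    d = _deviations(y)
    Wsp = W.to_sparse()
    s0 = float(Wsp.sum())
    n = y.shape[0]
    I = _global_i(d, Wsp, s0)
    # literal printed form: weight matrix also inside the denominator
    row_sums = np.asarray(Wsp.sum(axis=1)).ravel()
    I_printed = float(n * (d @ (Wsp @ d)) / (row_sums @ (d * d)))
    rng = np.random.default_rng(seed)
    sims = np.empty(n_perm)
    for k in range(n_perm):
        dp = d[rng.permutation(n)]
        sims[k] = _global_i(dp, Wsp, s0)
    mu, sd = sims.mean(), sims.std(ddof=1)
    z = (I - mu) / sd if sd > 0 else np.inf
    if I >= mu:
        p = (1 + np.sum(sims >= I)) / (n_perm + 1)
    else:
        p = (1 + np.sum(sims <= I)) / (n_perm + 1)
    return MoranResult(I=I, expected_I=-1.0 / (n - 1), z_score=float(z),
                       p_value=float(p), n_perm=n_perm, seed=seed,
                       I_as_printed=I_printed, perm_mean=float(mu),
                       perm_sd=float(sd))


def _quadrants(d: np.ndarray, lag: np.ndarray) -> np.ndarray:
    out = np.empty(d.shape[0], dtype=object)
    out[(d >= 0) & (lag >= 0)] = "H-H"
    out[(d < 0) & (lag < 0)] = "L-L"
    out[(d >= 0) & (lag < 0)] = "H-L"
    out[(d < 0) & (lag >= 0)] = "L-H"
    return out


def local_moran(y: Sequence[float], W: SpatialWeights, n_perm: int = 999,
                alpha: float = 0.05, seed: int = 0,
                positions: np.ndarray | None = None) -> LisaResult:
    """Local Moran's I with conditional-permutation pseudo p-values."""
    y = np.asarray(y, dtype=float)
    d = _deviations(y)
    n = y.shape[0]
    m2 = float(d @ d)
    lag = np.array([w @ d[nb] if len(nb) else 0.0
                    for nb, w in zip(W.neighbors, W.weights)])
    local_i = n * d * lag / m2
    rng = np.random.default_rng(seed)
    # one set of permutations of the n-1 "other" slots, shared across units
    perms = np.array([rng.permutation(n - 1) for _ in range(n_perm)])
    p = np.ones(n)
    for i in range(n):
        nb = W.neighbors[i]
        k = len(nb)
        if k == 0:
            continue
        others = np.delete(d, i)
        draw = others[perms[:, :k]]             # n_perm x k
        lag_sim = draw @ W.weights[i]
        sims = n * d[i] * lag_sim / m2
        if local_i[i] >= 0:
            p[i] = (1 + np.sum(sims >= local_i[i])) / (n_perm + 1)
        else:
            p[i] = (1 + np.sum(sims <= local_i[i])) / (n_perm + 1)
    quad = _quadrants(d, lag)
    label = np.where(p <= alpha, quad, "not significant").astype(object)
    # isolated units can never be significant
    for i in range(n):
        if len(W.neighbors[i]) == 0:
            label[i] = "not significant"
    return LisaResult(local_i=local_i, quadrant=quad, p_value=p,
                      cluster_label=label, alpha=alpha, n_perm=n_perm,
                      seed=seed, positions=positions)
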