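"""Geographic detector: stratified-heterogeneity drivers of the index.

Factor detection measures how much of the spatial variance of a response
y (here the quality index) a stratification of a candidate driver
explains:

    q = 1 - SSW / SST = 1 - sum_h N_h * sigma_h^2 / (N * sigma^2),

with population variances so that N_h * sigma_h^2 is the literal
within-stratum sum of squares; q is in [0, 1].  Interaction detection
compares q of the cross-stratification of two drivers with the single
q values and classifies the pair into five types (nonlinear/bilinear
enhancement, attenuation forms, independence).  Risk detection runs
pairwise Welch t-tests between stratum means of the response.

Continuous drivers are discretized with Jenks natural breaks (the study
uses 9 strata for continuous layers, 6 for land use, 2 for the binary
mining/subsidence/landform layers); categorical drivers keep their
categories.  Significance of q uses a seeded permutation test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .eeq_index import jenks_breaks


@dataclass
class Stratification:
    labels: np.ndarray            # stratum id 0..L-1 per sample
    L: int
    method: str                   # "natural_breaks" | "categorical"
    source_indicator: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        counts = np.bincount(self.labels, minlength=self.L)
        if (counts == 0).any():
            raise ValueError("empty stratum in stratification")


@dataclass
class FactorDetection:
    q: float
    SSW: float
    SST: float
    p_value: float
    strata: pd.DataFrame          # per stratum: n, mean, variance


@dataclass
class InteractionResult:
    q1: float
    q2: float
    q12: float
    interaction_type: str


@dataclass
class RiskDetection:
    stratum_means: pd.DataFrame   # stratum, n, mean
    pairs: pd.DataFrame           # h1, h2, mean_diff, t, df, p, significant
    alpha: float


def stratify(values: Sequence, k: int = 9,
             method: str = "natural_breaks",
             source_indicator: str = "") -> Stratification:
    """Discretize a driver into strata.

    ``natural_breaks`` reuses the Jenks classifier (k classes, empty strata
    impossible since breaks are data values); ``categorical`` maps each
    distinct label to one stratum.
    """
    if method == "categorical":
        _, labels = np.unique(np.asarray(values), return_inverse=True)
        L = int(labels.max()) + 1
        return Stratification(labels, L, method, source_indicator)
    if method != "natural_breaks":
        raise ValueError(f"unknown stratification method {method!r}")
    arr = np.asarray(values, dtype=float)
    breaks = jenks_breaks(arr, k)
    labels = np.searchsorted(breaks, arr, side="right")
    # renumber in case a class vanished through the subsample cap
    _, labels = np.unique(labels, return_inverse=True)
    return Stratification(labels, int(labels.max()) + 1, method, source_indicator)


def _sums_of_squares(y: np.ndarray, labels: np.ndarray, L: int):
    n_h = np.bincount(labels, minlength=L)
    sum_h = np.bincount(labels, weights=y, minlength=L)
    sum2_h = np.bincount(labels, weights=y * y, minlength=L)
    with np.errstate(invalid="ignore", divide="ignore"):
        ssw = float(np.sum(sum2_h - np.where(n_h > 0, sum_h ** 2 / np.maximum(n_h, 1), 0.0)))
    sst = float(np.sum(y * y) - y.sum() ** 2 / y.shape[0])
    return ssw, sst, n_h, sum_h


def factor_q(y: Sequence[float], strat: Stratification, n_perm: int = 999,
             seed: int = 0) -> FactorDetection:
    """q statistic with permutation significance (relabeling y)."""
    y = np.asarray(y, dtype=float)
    if y.shape[0] != strat.labels.shape[0]:
        raise ValueError("y and stratification are not aligned")
    ssw, sst, n_h, sum_h = _sums_of_squares(y, strat.labels, strat.L)
    if sst <= 0:
        raise ValueError("zero total variance: q undefined")
    q = 1.0 - ssw / sst
    p = float("nan")
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            yp = y[rng.permutation(y.shape[0])]
            ssw_p, _, _, _ = _sums_of_squares(yp, strat.labels, strat.L)
            if 1.0 - ssw_p / sst >= q:
                count += 1
        p = (1 + count) / (n_perm + 1)
    means = sum_h / n_h
    var_h = np.array([np.var(y[strat.labels == h]) for h in range(strat.L)])
    strata = pd.DataFrame({"stratum": np.arange(strat.L), "n": n_h,
                           "mean": means, "variance": var_h})
    return FactorDetection(q=float(q), SSW=ssw, SST=sst, p_value=p, strata=strata)


def cross_stratification(a: Stratification, b: Stratification) -> Stratification:
    """Stratification by distinct label pairs (a, b)."""
    if a.labels.shape != b.labels.shape:
        raise ValueError("stratifications are not aligned")
    pair = a.labels.astype(np.int64) * (b.L + 1) + b.labels
    _, labels = np.unique(pair, return_inverse=True)
    return Stratification(labels, int(labels.max()) + 1, "cross",
                          f"{a.source_indicator}*{b.source_indicator}")


_INDEP_TOL = 1e-9


def classify_interaction(q1: float, q2: float, q12: float) -> str:
    """Five-type interaction classification; exactly one branch fires."""
    lo, hi = min(q1, q2), max(q1, q2)
    if q12 < lo:
        return "nonlinear attenuation"
    if lo <= q12 <= hi:
        return "single-linear attenuation"
    if abs(q12 - (q1 + q2)) <= _INDEP_TOL:
        return "mutual independence"
    if q12 > q1 + q2:
        return "nonlinear enhancement"
    return "bilinear enhancement"


def interaction_detect(y: Sequence[float], strat_a: Stratification,
                       strat_b: Stratification) -> InteractionResult:
    """Compare the cross-stratification q with the single-factor q values."""
    y = np.asarray(y, dtype=float)
    q1 = factor_q(y, strat_a, n_perm=0).q
    q2 = factor_q(y, strat_b, n_perm=0).q
    q12 = factor_q(y, cross_stratification(strat_a, strat_b), n_perm=0).q
    return InteractionResult(q1=q1, q2=q2, q12=q12,
                             interaction_type=classify_interaction(q1, q2, q12))


def risk_detect(y: Sequence[float], strat: Stratification,
                alpha: float = 0.05) -> RiskDetection:
    """Pairwise Welch t-tests on stratum means, plus the mean profile."""
    y = np.asarray(y, dtype=float)
    groups = [y[strat.labels == h] for h in range(strat.L)]
    means = pd.DataFrame({
        "stratum": np.arange(strat.L),
        "n": [len(g) for g in groups],
        "mean": [g.mean() for g in groups],
    })
    rows = []
    for h1, h2 in itertools.combinations(range(strat.L), 2):
        g1, g2 = groups[h1], groups[h2]
        if len(g1) < 2 or len(g2) < 2:
            warnings.warn(f"stratum pair ({h1},{h2}) skipped: n < 2", stacklevel=2)
            continue
        if np.var(g1) == 0 and np.var(g2) == 0:
            t, df, p = (0.0, float(len(g1) + len(g2) - 2), 1.0) \
                if g1.mean() == g2.mean() else (np.inf, 1.0, 0.0)
        else:
            res = stats.ttest_ind(g1, g2, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        rows.append({"h1": h1, "h2": h2, "mean_diff": g1.mean() - g2.mean(),
                     "t": t, "df": df, "p": p, "significant": p <= alpha})
    return RiskDetection(stratum_means=means, pairs=pd.DataFrame(rows), alpha=alpha)


#: default stratum counts per indicator kind (continuous / land use / binary)
DEFAULT_STRATA = {"continuous": 9, "landuse": 6, "binary": 2}
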