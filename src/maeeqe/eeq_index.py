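"""Eco-environmental quality index (MAEEQI): weighted overlay, Jenks
five-grade classification and per-region area accounting.

MAEEQI is the cellwise weighted sum of the standardized indicator surfaces
with the projection-pursuit weights, so it lives in [0, 1] (weights are
non-negative and sum to 1).  The surface is classified into five grades,
1 = worse ... 5 = better, either with Jenks natural breaks recomputed from
the data or with user-supplied thresholds.  Grade intervals are
lower-closed / upper-open, except the top class which is closed above.

Jenks is implemented as exact dynamic programming (Fisher's optimal
univariate partition), so the breaks are deterministic and can be checked
against exhaustive search on small inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grid_model import Grid, RegionMask
from .standardization import StandardizedStack

#: cap above which Jenks runs on an evenly-spaced order-statistic subsample
_JENKS_MAX_N = 3000


@dataclass
class WeightVector:
    """Non-negative indicator weights summing to 1."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")

    def __getitem__(self, gid: str) -> float:
        return float(self.weights[gid])


@dataclass
class EEQSurface:
    index: Grid
    thresholds: np.ndarray  # 4 ascending breaks
    grades: Grid


def compute_maeeqi(std: StandardizedStack, w: WeightVector) -> Grid:
    """Weighted overlay of the standardized surfaces."""
    ids = std.stack.indicator_ids
    if set(ids) != set(w.weights):
        raise ValueError("weight vector does not match stack indicators")
    mask = std.stack.joint_valid_mask
    acc = np.zeros(std.stack.shape)
    for gid in ids:
        acc += w[gid] * np.where(mask, std.stack[gid].values, 0.0)
    values = np.where(mask, acc, np.nan)
    g0 = std.stack[ids[0]]
    return Grid(values, ~mask, g0.cell_size, g0.origin, g0.crs_label)


def jenks_breaks(values: Sequence[float], k: int) -> np.ndarray:
    """Natural-breaks class boundaries minimizing within-class SSD.

    Returns the k-1 lower bounds of classes 2..k (ascending), so that
    classifying with lower-closed intervals reproduces the optimal
    partition.  Exact Fisher dynamic programming; ties prefer the later
    split (smaller upper class).  Inputs beyond a size cap are reduced to
    an evenly spaced order-statistic subsample including min and max.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    if k < 2:
        raise ValueError("need at least 2 classes")
    if np.unique(arr).size < k:
        raise ValueError(f"need >= {k} distinct values for {k} classes")
    if arr.size > _JENKS_MAX_N:
        idx = np.unique(np.round(np.linspace(0, arr.size - 1, _JENKS_MAX_N)).astype(int))
        arr = arr[idx]
    n = arr.size
    s1 = np.concatenate(([0.0], np.cumsum(arr)))
    s2 = np.concatenate(([0.0], np.cumsum(arr * arr)))

    def seg_cost(i: np.ndarray, j: int):
        # SSD of arr[i:j] for vector of starts i
        cnt = j - i
        tot = s1[j] - s1[i]
        return (s2[j] - s2[i]) - tot * tot / cnt

    dp = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    cnt = np.arange(1, n + 1)
    dp[1][1:] = s2[1:] - s1[1:] * s1[1:] / cnt
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            i = np.arange(c - 1, j)
            cost = dp[c - 1][i] + seg_cost(i, j)
            # ties -> later split (smaller upper class)
            best = len(cost) - 1 - int(np.argmin(cost[::-1]))
            dp[c][j] = cost[best]
            split[c][j] = i[best]
    cuts = []
    j = n
    for c in range(k, 1, -1):
        j = split[c][j]
        cuts.append(j)
    cuts.reverse()
    return arr[np.array(cuts)]


def grade_surface(index: Grid, thresholds: Sequence[float]) -> Grid:
    """Classify the index with lower-closed / upper-open intervals.

    Grade g = 1 + number of thresholds <= value; grade 1 is worst, the top
    grade is closed above.
    """
    thr = np.asarray(thresholds, dtype=float)
    if thr.ndim != 1 or np.any(np.diff(thr) <= 0):
        raise ValueError("thresholds must be strictly ascending")
    vals = index.values[index.valid_mask]
    grades = np.searchsorted(thr, vals, side="right") + 1
    out = np.full(index.shape, np.nan)
    out[index.valid_mask] = grades
    return Grid(out, index.nodata_mask.copy(), index.cell_size, index.origin,
                index.crs_label)


def classify_index(index: Grid, thresholds: Sequence[float] | str = "jenks",
                   k: int = 5) -> EEQSurface:
    """Grade the index either with recomputed Jenks breaks or fixed ones."""
    if isinstance(thresholds, str):
        if thresholds != "jenks":
            raise ValueError(f"unknown threshold policy {thresholds!r}")
        thr = jenks_breaks(index.valid_values(), k)
    else:
        thr = np.asarray(thresholds, dtype=float)
    return EEQSurface(index=index, thresholds=thr,
                      grades=grade_surface(index, thr))


GRADE_LABELS = {1: "Worse", 2: "Bad", 3: "Medium", 4: "Good", 5: "Better"}


def grade_report(grades: Grid, regions: Sequence[RegionMask] | None = None,
                 n_grades: int = 5) -> pd.DataFrame:
    """Per-region area (km^2) and proportion (%) of each grade.

    Areas count valid cells times cell_size^2; proportions are of the
    region's valid area and sum to 100 per region.
    """
    if regions is None:
        regions = [RegionMask("all", np.ones(grades.shape, dtype=bool))]
    cell_km2 = grades.cell_size ** 2 / 1e6
    rows = []
    for region in regions:
        sel = region.mask & grades.valid_mask
        total = int(sel.sum())
        if total == 0:
            import warnings
            warnings.warn(f"region {region.name!r} has no valid cell", stacklevel=2)
        g = grades.values[sel].astype(int) if total else np.array([], dtype=int)
        counts = np.bincount(g, minlength=n_grades + 1)[1:n_grades + 1]
        for grade in range(1, n_grades + 1):
            cnt = int(counts[grade - 1])
            rows.append({
                "region": region.name,
                "grade": grade,
                "label": GRADE_LABELS.get(grade, str(grade)),
                "area_km2": cnt * cell_km2,
                "proportion_pct": 100.0 * cnt / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def grade_share(proportions: Mapping[int, float], grades: Sequence[int]) -> float:
    """Aggregate printed or computed per-grade proportions over a grade set."""
    return float(sum(proportions[g] for g in grades))
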