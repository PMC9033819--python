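"""Indicator standardization onto the common [0, 1] scale.

Quantitative indicators are min-max normalized over the valid cells, with a
per-indicator polarity: indicators that favour ecological quality
(precipitation, NDVI, aquifer specific yield, ...) map min->0 / max->1,
indicators that degrade it (evaporation, population density) are reversed.
Qualitative indicators (geomorphic type, land use, mining intensity,
surface subsidence) are first assigned an expert grade 1..5 per category
(grade 1 = worse, 5 = better) and the observed grades are then range
normalized with the same min-max rule.

The polarities and grade maps are configuration, not code: the shipped
defaults follow the conventional ecological reading of each indicator and
every entry can be overridden in the indicator-spec config.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .grid_model import Grid, GridStack, align_stack


class ZeroRangeError(ValueError):
    """All valid values identical; min-max normalization undefined."""


class DataError(ValueError):
    """Non-finite values among the valid cells."""


class MappingError(KeyError):
    """A category label is missing from the grade map."""


@dataclass(frozen=True)
class IndicatorSpec:
    """How one indicator is standardized.

    Exactly one of ``polarity`` (quantitative) or ``grade_map``
    (qualitative; category label or integer code -> grade 1..5) is set.
    """

    id: str
    name: str
    kind: str  # "quantitative" | "qualitative"
    polarity: str | None = None  # "positive" | "negative"
    grade_map: Mapping | None = None

    def __post_init__(self) -> None:
        if self.kind == "quantitative":
            if self.polarity not in {"positive", "negative"} or self.grade_map:
                raise ValueError(f"{self.id}: quantitative spec needs polarity only")
        elif self.kind == "qualitative":
            if self.polarity is not None or not self.grade_map:
                raise ValueError(f"{self.id}: qualitative spec needs grade_map only")
            if not all(g in {1, 2, 3, 4, 5} for g in self.grade_map.values()):
                raise ValueError(f"{self.id}: grades must be integers 1..5")
        else:
            raise ValueError(f"{self.id}: unknown kind {self.kind!r}")


@dataclass
class StandardizedStack:
    """Stack of [0, 1] surfaces plus the specs that produced them."""

    stack: GridStack
    specs: list[IndicatorSpec]


def normalize_quantitative(values: Sequence[float], polarity: str) -> np.ndarray:
    """Min-max normalize to [0, 1]; ``negative`` polarity reverses the scale."""
    arr = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise DataError("non-finite values in quantitative indicator")
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ZeroRangeError("constant indicator: min == max")
    if polarity == "positive":
        return (arr - lo) / (hi - lo)
    if polarity == "negative":
        return (hi - arr) / (hi - lo)
    raise ValueError(f"unknown polarity {polarity!r}")


def grade_qualitative(categories: Sequence, grade_map: Mapping) -> np.ndarray:
    """Map category labels (or integer codes) to expert grades 1..5."""
    out = np.empty(len(categories), dtype=float)
    for i, label in enumerate(categories):
        key = label
        if key not in grade_map:
            # grids carry categories as floats; retry as int code
            if isinstance(label, (float, np.floating)) and float(label).is_integer():
                key = int(label)
            if key not in grade_map:
                raise MappingError(f"category {label!r} not in grade map")
        out[i] = grade_map[key]
    return out


def standardize_stack(stack: GridStack, specs: Sequence[IndicatorSpec]) -> StandardizedStack:
    """Standardize every indicator surface onto [0, 1] over the joint mask."""
    spec_by_id = {s.id: s for s in specs}
    missing = [gid for gid in stack.indicator_ids if gid not in spec_by_id]
    if missing:
        raise ValueError(f"no IndicatorSpec for: {missing}")
    mask = stack.joint_valid_mask
    out: dict[str, Grid] = {}
    for gid in stack.indicator_ids:
        spec = spec_by_id[gid]
        grid = stack[gid]
        raw = grid.values[mask]
        if spec.kind == "quantitative":
            std = normalize_quantitative(raw, spec.polarity)
        else:
            grades = grade_qualitative(raw, spec.grade_map)
            std = normalize_quantitative(grades, "positive")
        values = np.full(grid.shape, np.nan)
        values[mask] = std
        out[gid] = Grid(values, ~mask, grid.cell_size, grid.origin, grid.crs_label)
    return StandardizedStack(align_stack(out), [spec_by_id[g] for g in stack.indicator_ids])


# ---------------------------------------------------------------------------
# Shipped defaults for the 13-indicator coal-field system (X1..X13).
# Grade 1 = worse ... 5 = better; all overridable through config.

GRADE_MAP_GEOMORPHIC = {
    "Middle-high elevation flood alluvial platform": 1,
    "Low elevation hill": 5,
}
GRADE_MAP_LANDUSE = {
    "Construction land": 1,
    "Desert land": 2,
    "Unused land": 2,
    "Cultivated land": 3,
    "Grassland": 4,
    "Woodland": 5,
}
GRADE_MAP_MINING = {
    "High-intensity exploitation": 1,
    "Unmined area": 5,
}
GRADE_MAP_SUBSIDENCE = {
    "Surface subsidence": 1,
    "Unsettled area": 5,
}

DEFAULT_POLARITY = {
    "X1": "positive",   # elevation
    "X2": "positive",   # slope
    "X3": "positive",   # aspect
    "X5": "positive",   # annual precipitation
    "X6": "negative",   # annual evaporation
    "X7": "positive",   # aquifer specific yield
    "X8": "positive",   # river-system distance
    "X10": "positive",  # NDVI
    "X12": "negative",  # population density
}

INDICATOR_NAMES = {
    "X1": "elevation", "X2": "terrain slope", "X3": "terrain aspect",
    "X4": "geomorphic type", "X5": "annual average precipitation",
    "X6": "annual average evaporation", "X7": "aquifer specific yield",
    "X8": "river system distance", "X9": "land use type", "X10": "NDVI",
    "X11": "mining intensity", "X12": "population density",
    "X13": "surface subsidence",
}
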