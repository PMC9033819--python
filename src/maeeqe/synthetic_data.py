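"""Synthetic 13-indicator raster scenes with planted ground truth.

The generator emulates the input stack of an arid-steppe coal-field
evaluation: nine quantitative surfaces built as spatially autocorrelated
Gaussian random fields (white noise smoothed by a moving-average filter),
cross-correlated through a shared latent elevation field (precipitation
and NDVI load positively on elevation, evaporation negatively), and four
qualitative mosaics — a two-band landform split, a smoothed land-use
mosaic, a contiguous high-intensity mined block on the western side, and
disc-shaped subsidence patches inside the mined block.  Mining leaves a
realistic footprint on the other layers: NDVI is depressed and land use
turns to construction inside the mined block.

The planted ground truth (latent weight vector, the latent quality field,
the mined-block mask, stratified-response parameters) is returned with
the scene so every downstream stage can be checked against construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .grid_model import Grid, GridStack, align_stack
from .standardization import (
    DEFAULT_POLARITY, INDICATOR_NAMES, IndicatorSpec, standardize_stack)
from .geodetector import Stratification

# integer category codes used in the qualitative layers
LANDFORM_CODES = {1: "Middle-high elevation flood alluvial platform",
                  2: "Low elevation hill"}
LANDUSE_CODES = {1: "Construction land", 2: "Desert land", 3: "Unused land",
                 4: "Cultivated land", 5: "Grassland", 6: "Woodland"}
MINING_CODES = {1: "High-intensity exploitation", 2: "Unmined area"}
SUBSIDENCE_CODES = {1: "Surface subsidence", 2: "Unsettled area"}

# grade maps keyed by the integer codes above (grade 1 = worse ... 5 = better)
GRADES_LANDFORM = {1: 1, 2: 5}
GRADES_LANDUSE = {1: 1, 2: 2, 3: 2, 4: 3, 5: 4, 6: 5}
GRADES_MINING = {1: 1, 2: 5}
GRADES_SUBSIDENCE = {1: 1, 2: 5}


@dataclass
class SceneConfig:
    """Study-scene parameters; defaults give a 10 x 20 km domain at 100 m
    resolution with a fifth of the area under high-intensity mining."""

    shape: tuple[int, int] = (100, 200)
    cell_size: float = 100.0
    autocorr_range: int = 6
    mined_fraction: float = 0.25
    subsidence_patches: int = 3
    subsidence_radius: int = 5
    noise_sd: float = 0.02
    ndvi_mining_loss: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] <= 0 or self.shape[1] <= 0:
            raise ValueError("shape must be positive")
        if not 0.0 <= self.mined_fraction <= 1.0:
            raise ValueError("mined_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for assertion in tests."""

    latent_weights: dict[str, float]
    latent_quality: np.ndarray
    mined_mask: np.ndarray
    config: SceneConfig

    def to_json(self) -> str:
        return json.dumps({
            "latent_weights": self.latent_weights,
            "latent_quality": self.latent_quality.tolist(),
            "mined_mask": self.mined_mask.astype(int).tolist(),
            "config": asdict(self.config),
        }, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        cfg = d["config"]
        cfg["shape"] = tuple(cfg["shape"])
        return cls(latent_weights=d["latent_weights"],
                   latent_quality=np.array(d["latent_quality"]),
                   mined_mask=np.array(d["mined_mask"], dtype=bool),
                   config=SceneConfig(**cfg))


def gaussian_field(shape: tuple[int, int], autocorr_range: int,
                   seed: int) -> Grid:
    """Smoothed white noise rescaled to [0, 1]; seeded and deterministic."""
    if autocorr_range < 0:
        raise ValueError("autocorr_range must be >= 0")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal(shape)
    if autocorr_range > 0:
        z = ndimage.uniform_filter(z, size=2 * autocorr_range + 1, mode="reflect")
    z = (z - z.min()) / (z.max() - z.min())
    return Grid(z, np.zeros(shape, dtype=bool))


def _zfield(shape, autocorr_range, seed) -> np.ndarray:
    """Zero-mean unit-variance smooth field (for latent mixing)."""
    v = gaussian_field(shape, autocorr_range, seed).values
    return (v - v.mean()) / v.std()


def _mix(base_z: np.ndarray, loading: float, shape, autocorr_range, seed):
    """Correlate a new field with the latent base at the given loading."""
    own = _zfield(shape, autocorr_range, seed)
    z = loading * base_z + np.sqrt(max(0.0, 1 - loading ** 2)) * own
    return (z - z.min()) / (z.max() - z.min())


def scene_specs() -> list[IndicatorSpec]:
    """Indicator specs matching the scene's layer encoding."""
    specs = []
    for gid, pol in DEFAULT_POLARITY.items():
        specs.append(IndicatorSpec(gid, INDICATOR_NAMES[gid], "quantitative",
                                   polarity=pol))
    specs.append(IndicatorSpec("X4", INDICATOR_NAMES["X4"], "qualitative",
                               grade_map=GRADES_LANDFORM))
    specs.append(IndicatorSpec("X9", INDICATOR_NAMES["X9"], "qualitative",
                               grade_map=GRADES_LANDUSE))
    specs.append(IndicatorSpec("X11", INDICATOR_NAMES["X11"], "qualitative",
                               grade_map=GRADES_MINING))
    specs.append(IndicatorSpec("X13", INDICATOR_NAMES["X13"], "qualitative",
                               grade_map=GRADES_SUBSIDENCE))
    order = [f"X{i}" for i in range(1, 14)]
    return sorted(specs, key=lambda s: order.index(s.id))


#: latent construction weights: mining, subsidence, precipitation and NDVI
#: carry the largest planted contributions, echoing a mining-dominated scene
LATENT_WEIGHTS = {
    "X1": 0.05, "X2": 0.04, "X3": 0.04, "X4": 0.05, "X5": 0.12, "X6": 0.08,
    "X7": 0.06, "X8": 0.05, "X9": 0.09, "X10": 0.11, "X11": 0.16,
    "X12": 0.05, "X13": 0.10,
}


def make_scene(config: SceneConfig | None = None) -> tuple[GridStack, GroundTruth]:
    """Generate the 13-layer stack and its ground truth."""
    cfg = config or SceneConfig()
    shape, cs = cfg.shape, cfg.cell_size
    nr, nc = shape
    seeds = np.random.SeedSequence(cfg.seed).generate_state(20) % (2 ** 31)

    elev_z = _zfield(shape, cfg.autocorr_range, int(seeds[0]))
    elev = (elev_z - elev_z.min()) / (elev_z.max() - elev_z.min())

    # terrain derivatives of the elevation surface
    gy, gx = np.gradient(elev)
    slope = np.hypot(gx, gy)
    slope = (slope - slope.min()) / (slope.max() - slope.min() + 1e-300)
    aspect = (np.arctan2(gy, gx) + np.pi) / (2 * np.pi)

    precip = _mix(elev_z, 0.7, shape, cfg.autocorr_range, int(seeds[1]))
    evap = _mix(-elev_z, 0.7, shape, cfg.autocorr_range, int(seeds[2]))
    sy = _mix(-elev_z, 0.4, shape, cfg.autocorr_range, int(seeds[3]))
    river = _mix(elev_z, 0.0, shape, cfg.autocorr_range, int(seeds[4]))
    popden = _mix(-elev_z, 0.3, shape, cfg.autocorr_range, int(seeds[5]))
    ndvi = _mix(elev_z, 0.6, shape, cfg.autocorr_range, int(seeds[6]))

    # contiguous mined block on the western side
    mined_cols = int(round(cfg.mined_fraction * nc))
    mined = np.zeros(shape, dtype=bool)
    mined[:, :mined_cols] = True
    mining_layer = np.where(mined, 1.0, 2.0)

    # mining footprint: NDVI depressed, land use turned to construction
    ndvi = np.clip(ndvi - cfg.ndvi_mining_loss * mined, 0.0, 1.0)

    rng = np.random.default_rng(int(seeds[7]))
    subsided = np.zeros(shape, dtype=bool)
    if mined_cols > 0:
        for _ in range(cfg.subsidence_patches):
            r0 = rng.integers(0, nr)
            c0 = rng.integers(0, max(1, mined_cols))
            rr, cc = np.ogrid[:nr, :nc]
            subsided |= (rr - r0) ** 2 + (cc - c0) ** 2 <= cfg.subsidence_radius ** 2
        subsided &= mined
    subsidence_layer = np.where(subsided, 1.0, 2.0)

    # land-use mosaic from quantiles of a smooth field, 6 classes
    lu_field = _zfield(shape, cfg.autocorr_range, int(seeds[8]))
    qs = np.quantile(lu_field, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
    landuse = np.searchsorted(qs, lu_field).astype(float) + 1.0
    construction = mined & (_zfield(shape, cfg.autocorr_range, int(seeds[9])) > 0.3)
    landuse[construction] = 1.0

    # platform (grade-1 landform) restricted to the highest ground so the
    # mined block stays the dominant binary structure of the scene
    landform = np.where(elev >= np.quantile(elev, 0.85), 1.0, 2.0)

    full = np.zeros(shape, dtype=bool)
    grids = {
        "X1": elev, "X2": slope, "X3": aspect, "X4": landform, "X5": precip,
        "X6": evap, "X7": sy, "X8": river, "X9": landuse, "X10": ndvi,
        "X11": mining_layer, "X12": popden, "X13": subsidence_layer,
    }
    stack = align_stack({gid: Grid(v, full.copy(), cs) for gid, v in grids.items()})

    # latent quality = planted weighted overlay + observation noise.
    # Qualitative layers enter through the fixed grade scale (g - 1) / 4,
    # which matches the range method whenever both extreme grades occur
    # and stays defined for single-category layers (e.g. mined_fraction 0).
    spec_by_id = {s.id: s for s in scene_specs()}
    latent = np.zeros(shape)
    for gid, w in LATENT_WEIGHTS.items():
        spec = spec_by_id[gid]
        vals = stack[gid].values
        if spec.kind == "qualitative":
            grades = np.vectorize(spec.grade_map.__getitem__)(vals.astype(int))
            layer = (grades - 1) / 4.0
        else:
            layer = (vals - vals.min()) / (vals.max() - vals.min())
        latent += w * layer
    latent += np.random.default_rng(int(seeds[10])).normal(
        scale=cfg.noise_sd, size=shape)

    truth = GroundTruth(latent_weights=dict(LATENT_WEIGHTS),
                        latent_quality=latent, mined_mask=mined, config=cfg)
    return stack, truth


def make_stratified_response(strat: Stratification, means: Sequence[float],
                             sd: float, seed: int = 0):
    """Gaussian response with planted per-stratum means.

    Returns ``(y, expected_q)`` where the analytic expectation is
    between-strata variance / (between + sd^2).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    means = np.asarray(means, dtype=float)
    if means.shape[0] != strat.L:
        raise ValueError("need one mean per stratum")
    rng = np.random.default_rng(seed)
    mu = means[strat.labels]
    y = mu + rng.normal(scale=sd, size=strat.labels.shape[0])
    n_h = np.bincount(strat.labels, minlength=strat.L)
    grand = float(np.average(means, weights=n_h))
    between = float(np.average((means - grand) ** 2, weights=n_h))
    expected_q = between / (between + sd ** 2) if (between + sd ** 2) > 0 else 0.0
    return y, expected_q
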