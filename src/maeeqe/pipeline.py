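"""End-to-end orchestration of the quality-evaluation workflow.

standardize -> projection-pursuit weights -> MAEEQI -> Jenks grading and
area report -> unit resampling + Moran/LISA -> geographic detector ->
management zoning, with one master seed fanned out deterministically to
every stochastic stage.  Identical config + seed reproduces every
serialized artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .grid_model import (Grid, GridStack, RegionMask, align_stack,
                         flatten_valid, read_grid, write_grid)
from .standardization import IndicatorSpec, standardize_stack
from .projection_pursuit import GAParams, optimize_direction
from .eeq_index import (WeightVector, classify_index, compute_maeeqi,
                        grade_report)
from .spatial_stats import (build_weights, global_moran, local_moran,
                            resample_to_units)
from .geodetector import (Stratification, factor_q, interaction_detect,
                          risk_detect, stratify)
from .zoning import classify_zones

log = logging.getLogger("maeeqe")

_ZONE_CODES = {"none": 0, "management": 1, "close_attention": 2, "protective": 3}


@dataclass
class PipelineConfig:
    """Resolved workflow settings; every default is explicit on disk.

    The analysis-scale defaults mirror the study configuration: 500 m
    analysis units, queen contiguity with row standardization, 999
    permutations at alpha = 0.05, nine Jenks strata for continuous
    drivers (qualitative drivers keep their categories), and the GA
    settings carried by :class:`GAParams`.
    """

    unit_size: float = 500.0
    min_coverage: float = 0.5
    weights_scheme: str = "queen"
    row_standardize: bool = True
    n_perm: int = 999
    alpha: float = 0.05
    thresholds: Sequence[float] | str = "jenks"
    n_grades: int = 5
    R: float | str = "auto"
    continuous_strata: int = 9
    ga: GAParams = field(default_factory=GAParams)
    seed: int = 0

    def resolved(self) -> dict:
        d = asdict(self)
        if not isinstance(d["thresholds"], str):
            d["thresholds"] = [float(v) for v in d["thresholds"]]
        return d


def _stage_seeds(master: int) -> dict[str, int]:
    names = ["ga", "moran", "lisa", "factor_q"]
    state = np.random.SeedSequence(master).generate_state(len(names)) % (2 ** 31)
    return {name: int(s) for name, s in zip(names, state)}


def _config_hash(resolved: dict) -> str:
    return hashlib.sha256(
        json.dumps(resolved, sort_keys=True).encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(stack: GridStack, specs: Sequence[IndicatorSpec],
                 config: PipelineConfig, outdir: str | Path,
                 regions: Sequence[RegionMask] | None = None) -> dict:
    """Run every stage and write the artifact directory.

    Returns a dict of in-memory stage results keyed by stage name; the
    serialized artifacts live under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    resolved["ga"]["seed"] = config.ga.seed
    seeds = _stage_seeds(config.seed)
    chash = _config_hash(resolved)
    provenance = {"tool": "maeeqe", "version": __version__,
                  "config_hash": chash, "master_seed": config.seed,
                  "stage_seeds": seeds}
    _write_json(outdir / "resolved_config.json",
                {"config": resolved, "provenance": provenance})

    # 1 -- standardization ---------------------------------------------------
    log.info("stage standardize: %d indicators", len(stack))
    std = standardize_stack(stack, specs)
    std_dir = outdir / "standardized"
    std_dir.mkdir(exist_ok=True)
    for gid in std.stack.indicator_ids:
        write_grid(std.stack[gid], std_dir / f"{gid}.asc")

    # 2 -- projection-pursuit weights ---------------------------------------
    sample = flatten_valid(std.stack)
    ga = GAParams(**{**asdict(config.ga), "seed": seeds["ga"]})
    log.info("stage weights: GA on n=%d, m=%d (seed %d)", sample.n, sample.m,
             ga.seed)
    proj = optimize_direction(sample, ga, R=config.R)
    _write_json(outdir / "projection.json",
                {**proj.to_dict(), "provenance": provenance})
    weights = WeightVector(proj.weight_map())

    # 3 -- MAEEQI, grading, area report -------------------------------------
    index = compute_maeeqi(std, weights)
    surface = classify_index(index, config.thresholds, config.n_grades)
    write_grid(surface.index, outdir / "maeeqi.asc")
    write_grid(surface.grades, outdir / "grades.asc")
    _write_json(outdir / "thresholds.json",
                {"thresholds": [float(t) for t in surface.thresholds],
                 "provenance": provenance})
    report = grade_report(surface.grades, regions, config.n_grades)
    _write_csv(report, outdir / "grade_report.csv")

    # 4 -- spatial autocorrelation on analysis units ------------------------
    lattice = resample_to_units(surface.index, config.unit_size,
                                config.min_coverage)
    W = build_weights(lattice, config.weights_scheme, config.row_standardize)
    log.info("stage moran: %d units of %.0f m", lattice.n, config.unit_size)
    moran = global_moran(lattice.values, W, config.n_perm, seeds["moran"])
    _write_json(outdir / "moran.json", {
        "I": moran.I, "expected_I": moran.expected_I, "z_score": moran.z_score,
        "p_value": moran.p_value, "n_perm": moran.n_perm,
        "I_as_printed": moran.I_as_printed, "n_units": lattice.n,
        "provenance": provenance})
    lisa = local_moran(lattice.values, W, config.n_perm, config.alpha,
                       seeds["lisa"], positions=lattice.positions)
    d = lattice.values - lattice.values.mean()
    lag = np.array([w @ d[nb] if len(nb) else 0.0
                    for nb, w in zip(W.neighbors, W.weights)])
    lisa_df = pd.DataFrame({
        "unit": np.arange(lattice.n),
        "row": lattice.positions[:, 0], "col": lattice.positions[:, 1],
        "value": lattice.values, "deviation": d, "lag": lag,
        "local_i": lisa.local_i, "quadrant": lisa.quadrant,
        "p": lisa.p_value, "label": lisa.cluster_label,
    })
    _write_csv(lisa_df, outdir / "lisa.csv")
    _write_csv(lisa_df[["unit", "deviation", "lag"]],
               outdir / "moran_scatter.csv")

    # 5 -- geographic detector on the fine-cell samples ---------------------
    y = index.values[index.valid_mask]
    spec_by_id = {s.id: s for s in specs}
    strats: dict[str, Stratification] = {}
    for gid in stack.indicator_ids:
        layer = stack[gid].values[index.valid_mask]
        if spec_by_id[gid].kind == "qualitative":
            strats[gid] = stratify(layer, method="categorical",
                                   source_indicator=gid)
        else:
            strats[gid] = stratify(layer, k=config.continuous_strata,
                                   method="natural_breaks", source_indicator=gid)
    log.info("stage geodetector: %d drivers, %d samples", len(strats), len(y))
    factor_rows = []
    for gid, strat in strats.items():
        det = factor_q(y, strat, config.n_perm, seeds["factor_q"])
        factor_rows.append({"indicator": gid, "q": det.q, "p": det.p_value,
                            "L": strat.L})
    factor_df = pd.DataFrame(factor_rows).sort_values(
        "q", ascending=False, kind="stable").reset_index(drop=True)
    _write_csv(factor_df, outdir / "geodetector_factor.csv")

    inter_rows = []
    ids = stack.indicator_ids
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            res = interaction_detect(y, strats[a], strats[b])
            inter_rows.append({"a": a, "b": b, "q1": res.q1, "q2": res.q2,
                               "q12": res.q12, "type": res.interaction_type})
    inter_df = pd.DataFrame(inter_rows)
    _write_csv(inter_df, outdir / "geodetector_interaction.csv")

    risk_frames = []
    for gid, strat in strats.items():
        risk = risk_detect(y, strat, config.alpha)
        means = risk.stratum_means.copy()
        means.insert(0, "indicator", gid)
        risk_frames.append(means)
    _write_csv(pd.concat(risk_frames, ignore_index=True),
               outdir / "geodetector_risk_means.csv")

    # 6 -- zoning ------------------------------------------------------------
    zoning = classify_zones(lisa)
    zone_df = pd.DataFrame({
        "unit": np.arange(lattice.n),
        "row": lattice.positions[:, 0], "col": lattice.positions[:, 1],
        "zone": zoning.zones,
    })
    _write_csv(zone_df, outdir / "zoning.csv")
    unit_area_km2 = (config.unit_size ** 2) / 1e6
    _write_json(outdir / "zoning_summary.json", {
        "counts": zoning.counts,
        "area_km2": {z: c * unit_area_km2 for z, c in zoning.counts.items()},
        "provenance": provenance})
    zr = np.full(lattice.lattice_shape, np.nan)
    codes = np.array([_ZONE_CODES[z] for z in zoning.zones], dtype=float)
    zr[lattice.positions[:, 0], lattice.positions[:, 1]] = codes
    zone_grid = Grid(zr, np.isnan(zr), config.unit_size, stack.origin)
    write_grid(zone_grid, outdir / "zones.asc")

    return {"standardized": std, "sample": sample, "projection": proj,
            "weights": weights, "surface": surface, "report": report,
            "lattice": lattice, "moran": moran, "lisa": lisa,
            "factor": factor_df, "interaction": inter_df, "zoning": zoning}


def load_stack_from_paths(paths: Mapping[str, str | Path]) -> GridStack:
    """Read pre-aligned indicator rasters into a stack."""
    return align_stack({gid: read_grid(p) for gid, p in paths.items()})
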