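# maeeqe

Eco-environmental quality evaluation for coal-mining regions from stacks of
co-registered raster indicators.

Mining regions in arid western China face a sharp trade-off between coal
extraction and the stability of fragile desert–oasis ecosystems. `maeeqe`
implements a quantitative evaluation workflow for such regions: it fuses 13
terrain, climate, hydrology, land-use, vegetation and mining-activity
indicators into a single **mining-area eco-environmental quality index
(MAEEQI)**, maps and grades the index, characterizes its spatial pattern,
identifies its drivers, and converts local clusters into management zones.
It is aimed at researchers and mine-environment analysts who have (or want
to simulate) a co-registered raster indicator stack.

## Method

1. **Standardization.** Quantitative indicators are min-max normalized with
   a polarity (for beneficial indicators `X = (x − min)/(max − min)`, for
   detrimental ones `X = (max − x)/(max − min)`); qualitative indicators
   (geomorphic type, land use, mining intensity, surface subsidence) get
   expert grades 1–5 which are then range-normalized.
2. **Projection-pursuit weighting.** The standardized sample matrix is
   projected onto a unit direction *c*, `V_i = Σ_j c_j x_ij`, and a
   real-coded genetic algorithm maximizes the projection index
   `Q(c) = S(c)·D(c)` — overall spread times within-window density
   `D = Σ_ij (R − r_ij)·1{r_ij < R}`, `r_ij = |V_i − V_j|`, `R = 0.1·S` —
   subject to `Σ c_j² = 1`. Indicator weights are `u_j = c_j²`.
3. **Index and grading.** `MAEEQI = Σ_j u_j X_j ∈ [0, 1]`, classified into
   five grades (worse → better) with exact Jenks natural breaks, with
   per-region area/proportion reports.
4. **Spatial pattern.** The index is aggregated to square analysis units
   (default 500 m), and global/local Moran's *I* with permutation
   inference yields the Moran scatter and LISA cluster map
   (H-H, L-L, H-L, L-H).
5. **Drivers.** The geographic detector measures each indicator's
   explanatory power `q = 1 − SSW/SST` over Jenks or categorical strata,
   classifies pairwise interactions into five types, and runs Welch
   t-tests between stratum means (risk detection).
6. **Zoning.** Significant L-L clusters → management area, H-H → close
   attention area, H-L/L-H outliers → protective area.

Because real indicator stacks of this kind are rarely shareable, the
package ships a first-class synthetic scene generator
(`maeeqe.synthetic_data`) producing 13 correlated indicator rasters with a
contiguous mined block and planted ground truth, so the whole pipeline is
testable end to end.

## Worked example

```bash
maeeqe simulate --rows 100 --cols 200 --seed 1 demo/scene
maeeqe run-all --seed 1 demo/scene demo/out
```

prints

```
scene with 13 indicators written to demo/scene
artifacts written to demo/out
```

and `demo/out/` then holds the standardized layers, projection weights,
`maeeqi.asc`/`grades.asc`, the grade report, Moran/LISA tables, detector
results and the zoning map. Inspecting the key numbers of that run:

```text
global Moran's I = 0.941            # strongly clustered quality surface
factor detection (top of 13):
  indicator        q      p
  X11 (mining)   1.000  0.001       # mining intensity ranks first
  X10 (NDVI)     0.821  0.001
zoning: {management: 160, close_attention: 262, protective: 0, none: 378}
mined-block grade report: 57.5 % Worse + 42.5 % Bad
```

The mined block dominates the scene: the projection pursuit concentrates
its weight on mining intensity, the index is lowest inside the block
(graded Worse/Bad), the quality surface is significantly positively
autocorrelated (I = 0.941, pseudo-p = 0.001), the detector ranks mining
intensity first among the 13 drivers, and the block's L-L cluster becomes
the management zone — the qualitative structure expected of a
high-intensity mining area.

Every stage is also available as a library call (`make_scene`,
`standardize_stack`, `optimize_direction`, `compute_maeeqi`,
`classify_index`, `global_moran`, `local_moran`, `factor_q`,
`interaction_detect`, `risk_detect`, `classify_zones`, `run_pipeline`) and
as individual CLI subcommands (`standardize`, `weights`, `index`,
`moran`).

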