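# Methods notes

## Model and assumptions

The package evaluates eco-environmental quality over a rectangular raster
domain from 13 co-registered single-band indicators (X1–X13: elevation,
slope, aspect, geomorphic type, precipitation, evaporation, aquifer
specific yield, river-system distance, land use, NDVI, mining intensity,
population density, surface subsidence). Inputs must be pre-aligned —
identical shape, cell size and origin; the package refuses mismatched
geometries rather than resampling, because silent reprojection would
corrupt a multi-criteria overlay. Any cell missing in any indicator is
excluded from the whole analysis (joint valid mask): the projection step
needs complete sample rows, and partial rows would bias min-max ranges.

### Standardization

Quantitative indicators use min-max normalization over the valid cells of
the current scene (not fixed global constants — the transform is defined
on the sample), with a configurable polarity. The shipped defaults treat
precipitation, specific yield, NDVI, elevation, slope, aspect and river
distance as beneficial and evaporation and population density as
detrimental; these are ecological conventions, not facts about every
region, and are configuration. Qualitative indicators are mapped to
expert grades 1–5 (worse → better) and the observed grades are then
range-normalized. The shipped grade maps put high-intensity
mining/subsided ground/construction land at grade 1 and unmined/unsettled
ground/woodland at grade 5; desert and unused land are both graded 2
(ecologically comparable bare surfaces); the binary geomorphic split uses
the extreme grades {1, 5}. A constant indicator is a hard error
(zero-range): it carries no information and its normalization is
undefined.

### Projection-pursuit weighting

Weights come from a one-dimensional projection pursuit: maximize
Q(c) = S(c)·D(c) over unit directions, where S is the sample standard
deviation (n − 1 denominator) of the projected values and D is the
windowed pair density — the literal double sum over all ordered pairs,
including i = j, of (R − r_ij) for r_ij strictly inside the window R.
The diagonal therefore contributes n·R and the step function satisfies
f(0) = 0. D is evaluated with a sort/prefix-sum identity that equals the
double sum exactly but costs O(n log n) instead of O(n²).

The window radius is R = 0.1·S(c), recomputed for each candidate
direction (a fixed numeric override is accepted). This is the prevailing
convention in the projection-pursuit literature; nothing in the index
itself pins R down, and results can be sensitive to it (see
*Limitations*).

The optimizer is a real-coded genetic algorithm on the unit sphere:
tournament selection (size 2), arithmetic crossover, Gaussian mutation
(σ = 0.1), renormalization of every offspring onto the sphere, and
elitism. Defaults: population 400, crossover probability 0.8, mutation
probability 0.3, 200 elites, at most 200 generations, early stop after 30
generations without relative improvement above 1e-8. Elitism makes the
best-Q trace non-decreasing and, for a fixed seed, extending the run can
only improve the result. For n > 5,000 samples the objective is evolved
on a seeded random subsample of 2,000 cells (D is quadratic in content if
evaluated naively and even the fast form benefits), and the final Q of
the winning direction is recomputed on the full sample. Weights are the
squared direction components, u_j = c_j², hence non-negative and summing
to 1, and invariant under the sign flip c → −c that leaves Q unchanged.

### Index, grading, areas

MAEEQI is the cellwise weighted sum of the standardized surfaces, so it
lives in [0, 1] and is monotone in every indicator. Grading uses Jenks
natural breaks implemented as exact dynamic programming (Fisher's optimal
univariate partition) — deterministic and checkable against exhaustive
search — rather than the common heuristic re-seeding variant. Ties in
the dynamic program prefer the later split (smaller top class). For more
than 3,000 values the breaks are computed on an evenly spaced
order-statistic subsample including the extremes; the partition cost of
the subsample optimum is indistinguishable from the full optimum at the
surface resolutions used here. Grade intervals are lower-closed /
upper-open with the top class closed above, so a value equal to a break
belongs to the class above it; fixed external break values can be
supplied instead of recomputed ones. Areas are valid-cell counts times
cell_size² (reported in km²), and per-region proportions always sum to
100 %.

### Spatial autocorrelation

The index is aggregated to square units (default 500 m) by the mean of
valid fine cells; units with less than 50 % valid coverage are dropped to
stabilize border means. Contiguity is queen by default (rook available),
row-standardized. Global Moran's I uses the standard normalization
I = (n/S0)·Σ_ij w_ij d_i d_j / Σ d_i², which is the quantity bounded by
[−1, 1] on row-standardized lattices; the textbook variant that folds the
weights into the denominator is computed alongside (`I_as_printed`) for
transparency. Inference is by random relabeling (default 999
permutations, seeded), reporting a one-sided pseudo p toward the observed
side and a permutation z-score; the permutation-null mean matches the
analytic expectation −1/(n − 1).

Local Moran uses I_i = n·d_i·Σ_j w_ij d_j / Σ_k d_k² with conditional
permutation: unit i is held fixed and its neighbors are resampled without
replacement from the other n − 1 units, reusing one seeded set of
permutations across units. Quadrants come from the signs of the deviation
and its spatial lag (zero deviations count as high, which is immaterial
since such units have I_i = 0 and are never significant); cluster labels
are assigned only below α (default 0.05). With row-standardized weights
the local statistics average exactly to the global I, which the tests
verify.

### Geographic detector

Factor detection: q = 1 − SSW/SST with population variances, so
N_h·σ_h² telescopes to the literal within-stratum sum of squares;
q ∈ [0, 1] and singleton strata are legal (zero within variance).
Significance is a seeded permutation test on relabeled responses (999 by
default) — assumption-free and exactly reproducible, in preference to a
noncentral-F approximation. Continuous drivers are discretized with Jenks
into 9 strata by default; categorical drivers keep their categories
(6 for land use, 2 for the binary layers). Interaction detection computes
q on the cross-stratification (distinct label pairs), which refines both
inputs, so q12 ≥ max(q1, q2) up to rounding — interactions can only look
like enhancement unless strata collapse. Classification uses the standard
five types; the "mutual independence" branch fires within a tolerance of
1e-9 on |q12 − (q1 + q2)| and is checked before the strict "greater than
the sum" branch, since exact equality of floats never occurs. Risk
detection runs two-sided Welch t-tests (Welch–Satterthwaite degrees of
freedom, via scipy) on all stratum pairs with n_h ≥ 2 and returns the
stratum mean profile.

### Zoning

A pure function of the LISA labels: significant L-L → management,
H-H → close attention, H-L/L-H → protective, everything else an explicit
"none" so zone counts partition the retained units.

## Synthetic scenes

The generator emulates an arid mining region: smooth spatially
autocorrelated quantitative fields (white noise convolved with a uniform
filter — simple and sufficient for Moran/LISA testing, in preference to
spectral synthesis), cross-correlated through a shared latent elevation
field (precipitation and NDVI load +0.7/+0.6, evaporation −0.7);
slope/aspect derived from the elevation gradient; a contiguous western
mined block (default 25 % of the domain) with an NDVI depression of 0.35
and construction-land conversion inside it; disc-shaped subsidence
patches confined to the block; a six-class land-use mosaic from quantiles
of a smooth field; a two-band landform split placing the grade-1 platform
on the highest 15 % of ground. A planted latent quality field (fixed
weighted overlay plus Gaussian noise, default σ = 0.02) and the block
mask are returned as ground truth. Scenes are fully deterministic per
seed, with layer-level seeds derived from the scene seed.

What the scenes do **not** emulate: sensor radiometry, registration
error, nodata holes, anisotropic or long-range trends beyond the latent
coupling, and realistic class geometry for land use. Passing tests on
these scenes demonstrate the correctness and determinism of the
machinery and the recoverability of planted structure, not performance
on real imagery.

A deliberate property of the default scene: because the standardized
mining layer is exactly binary and the projection index strongly rewards
exact ties inside the R-window, the genetic algorithm concentrates nearly
all weight on mining intensity — the most balanced binary structure in
the scene — and the quality index is dominated by the mined/unmined
contrast. This makes the mining-first driver ranking a structural
consequence of the construction, which is what the recovery tests assert.

## Parameter defaults

| Parameter | Default | Unit | Notes |
|---|---|---|---|
| GA population / crossover / mutation / elites | 400 / 0.8 / 0.3 / 200 | – | study-scale configuration |
| GA generations / stall | 200 / 30 | generations | stall at relative ΔQ < 1e-8 |
| Window radius R | 0.1·S(c) | index units | per-candidate; numeric override |
| Objective subsample | 2,000 above n = 5,000 | cells | seeded; final Q on full sample |
| Grades | 5, Jenks | – | or fixed external breaks |
| Analysis unit | 500 | m | must be a multiple of cell size |
| Unit coverage floor | 0.5 | fraction | border stabilization |
| Contiguity | queen, row-standardized | – | rook available |
| Permutations / α | 999 / 0.05 | – | global, local and q tests |
| Continuous strata | 9 (Jenks) | – | categorical layers keep categories |
| Scene | 100×200 cells at 100 m, mined 0.25 | – | ~200 km² domain |

All of these are configuration, not constants; the resolved configuration
(with the per-stage seeds fanned out from the master seed through a
`SeedSequence`) is written into every artifact directory together with a
config hash.

## Problem sizes

The shipped tests and the acceptance script run on 100×200-cell scenes
(20,000 samples, 800 analysis units), 5×5 oracle lattices, n = 10,000
stratified responses, m = 2 sweep problems with 10⁴ angles, and 20×20
LISA lattices with 999 permutations — sizes chosen so the complete suite
executes in a few minutes on one CPU while still exercising the
subsampling and permutation paths.

## Known limitations

- The projection index with R = 0.1·S degenerates toward the most
  balanced exactly-binary standardized layer when one exists; with
  all-continuous inputs the optimum is a genuine mixture. Analysts who
  want distributed weights over mixed stacks should supply a larger fixed
  R or pre-jitter binary layers; the package deliberately does neither by
  default.
- Jenks on very large surfaces is computed on a 3,000-point order
  subsample; pathological distributions could shift a break by one data
  value.
- Conditional permutation reuses one permutation set across units (the
  standard computational shortcut); p-values across units are therefore
  not independent draws.
- ESRI ASCII and single-band GeoTIFF only; no reprojection, multi-band
  files, or vector data beyond boolean region masks.
- The q permutation test and the Welch tests treat cells as independent
  samples; spatial autocorrelation inflates their effective significance,
  as it does in the standard practice this mirrors.
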