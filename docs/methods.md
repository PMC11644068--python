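# Methods

## Scope and model

`agbfusion` estimates plot-scale potato above-ground biomass (AGB, ton/ha)
from UAV multispectral + RGB imagery fused with agro-meteorological and
phenological covariates. The statistical core is a comparison grid: six
regression algorithms × all 31 non-empty subsets of the five feature groups
{VIs, Texture, GDD, CC, GPR}, under two feature-selection routes, scored on a
single stratified holdout. The package takes no position on which model wins
in general; it provides the machinery to run the comparison reproducibly and
verifies on synthetic data that phenology-aware fusion resolves the
cultivar ambiguity that spectral features alone cannot.

## Feature definitions

**Band semantics.** The six multispectral slots map to roles blue, green,
panchromatic, red, red edge, NIR as band1..band6. This assignment is
config-overridable (`BandStack.band_roles`); sensor vendor tables sometimes
swap the red-edge/NIR labels, so the roles, not the slot numbers, are
authoritative throughout the code.

**Vegetation indices.** 14 indices computed from plot-mean reflectance
(zonal mean over the plot polygon, pixel-center point-in-polygon test).
Two published formulas needed dialect decisions, both config-exposed:

- *NDI* is implemented as (NIR − RE)/(NIR + R); the alternative
  (NIR − RE)/(NIR + RE) denominator is selectable (`ndi_dialect`).
- *MCARI2* uses the canonical form
  1.5·[2.5(NIR−R) − 1.3(NIR−G)] / √((2·NIR+1)² − (6·NIR − 5√R) − 0.5);
  a variant with the 1.52 factor applied to the first difference only is
  selectable (`mcari2_dialect`).
- *TDVI* is implemented as (0.5 + NDVI)², following the index table this
  bank reproduces rather than the older 1.5(NIR−R)/√(NIR²+R+0.5) form.

GRNDVI, (NIR − (G+R))/(NIR + (G+R)), is available as an optional fifteenth
index. Zero-denominator indices are returned as NaN and excluded listwise
during modeling.

**GLCM texture.** Per multispectral band, over the in-polygon bounding
patch: equal-width quantization to 32 gray levels between the patch min and
max (hence invariance to additive shifts), symmetric normalized
co-occurrence matrix at distance 1, features averaged over the four angles
{0°, 45°, 90°, 135°}. The eight statistics (with P the matrix, μ, σ² from
the marginal): ME = Σ i·P, VA = Σ (i−μ)²·P, DI = Σ |i−j|·P,
CON = Σ (i−j)²·P, HO = Σ P/(1+(i−j)²), SE = Σ P², COR = Σ (i−μ)(j−μ)P/σ²
(defined as 1 when σ² = 0), EN = −Σ P·log P with natural log and
0·log 0 = 0. The matrix construction and statistics are implemented
in-package because this exact dialect (min–max binning, four-angle feature
averaging, natural-log entropy) is part of the contract; the test suite
cross-checks the pair counting against `skimage.feature.graycomatrix` and
every statistic against literal double-loop oracles at 1e-12.

**Canopy cover.** Excess green (ExG = 2G − R − B) on the RGB rendering by
default (per-pixel NDVI selectable), thresholded by Otsu on the in-polygon
values. Otsu on a *unimodal* histogram — an all-soil or closed-canopy plot —
bisects the sensor noise of a single material and is badly wrong, so the
split is accepted only when the two classes it produces are separated by at
least 3.2 pooled within-class standard deviations; otherwise a fixed
fallback threshold (ExG 10 DN, NDVI 0.4) is used with a warning. The 3.2
default sits between the separation Otsu produces on one Gaussian mode
(≈2.65 independent of its width) and the separation of genuinely mixed
plots under the default endmember contrast (≥4).

**GDD.** Daily increments (T_max + T_min)/2 − T_b are floored at zero by
default — the standard agronomic convention; the raw signed sum is available
via `allow_negative=True`. The base temperature defaults to 7 °C for potato
and is an explicit field of the cultivar catalog.

**GPR.** T_1/T_O with T_1 = days after emergence and T_O the cultivar's
total growth-period days. Values are stored full-precision and rounded to
two decimals only for reporting. GPR > 1 (late harvest) warns but is not
clipped. When emergence dates are unknown, `anchor_t1` reconstructs T_1 at
later flights from a known first-flight GPR:
T_1 = round(GPR_S1 × T_O) + calendar gap. This reconstruction reproduces the
published cultivar timetable at two decimals for eleven of the twelve cells
of the three anchor cultivars; the mid-maturing cultivar's third-stage cell
is printed one hundredth lower than any emergence-date-consistent timeline
allows (49/95 = 0.5158), and the corresponding acceptance assertion is left
failing rather than special-cased.

## Feature selection

**Boruta** (authored in-package on `sklearn.ensemble.RandomForestRegressor`):
each iteration re-permutes every candidate into a shadow column, fits a
200-tree forest on real + shadow features, and scores a hit when a real
feature's importance beats the shadow maximum. After `max_iter` iterations
(default 100) a two-sided binomial test of hits against p = 0.5,
Bonferroni-corrected across candidates at α = 0.05, confirms or rejects;
undecided features are resolved by comparing median importance to the median
shadow maximum (a flag keeps them tentative instead). All internals
(tree count, iteration cap, α) are exposed; none is prescribed by the study
design, so the defaults follow the original Boruta algorithm. Note that the
binomial test controls false positives, while the median-based resolution of
tentative features — like the original algorithm's rough-fix — can promote a
feature whose spurious sample correlation with the target persists across
iterations; on all-noise data with resolution enabled an occasional
confirmation is expected behaviour, not a defect.

**VIF screen** (after Boruta, on its confirmed set): iteratively drop the
highest-VIF feature until all VIF = 1/(1−R²) ≤ 10, computed via
`statsmodels` with an intercept; exact collinearity yields VIF = ∞ and is
dropped first, ties break toward the lexicographically later name.

**Pearson route**: |r| against the target on pooled rows, keep the top 5
vegetation indices and top 3 texture features; ties at the cut break by
feature name. Constant features are auto-rejected.

## Models and evaluation

RF: 500 trees, unlimited depth. PLSR: components chosen by 5-fold CV over
1..10 (capped by the feature count). Ridge: λ by generalized CV on a log
grid 10⁻³..10³. Lasso: λ path by 5-fold CV. MLR rejects singular designs;
SLR uses the single train-set feature with the highest |r|. Standardization
for PLSR/Ridge/Lasso is fit on the training partition inside the pipeline.
The split is a single random holdout (train fraction 2/3), stratified by
growth stage; a grouped-by-plot or repeated-holdout analysis is possible by
looping over seeds, as the acceptance suite does. Metrics: R², RMSE, MAE,
and rRMSE = RMSE/ȳ, reported dimensionless.

## Synthetic study generator

The generator emulates the study conditions the pipeline targets, not any
particular real field:

- **Designs**: E1 = 2 cultivars × 3 densities (52 500 / 60 000 / 75 000
  plants/ha) × 3 blocks = 18 plots; E2 = 2 cultivars × 5 N rates
  (0/50/100/250/400 kg/ha) × 4 blocks = 40; E3 = 1 cultivar × 3 N × 4 K × 3
  blocks = 36. Four flights per experiment (early July to mid August 2023)
  give 376 plot-date samples.
- **Cultivars**: growth periods 75 (Z5, Z35), 95 (Z27), 105 (Z19) and 110
  (Z49) days — a 35-day maturity span; emergence dates around 15 June 2023,
  back-computed from the first-flight growth stages.
- **Latent AGB**: logistic in GPR (midpoint 0.45, steepness 8), asymptote
  8 ton/ha at reference management, modulated by N (Michaelis–Menten,
  half-saturation 100 kg/ha, floor 0.55), K (weakly), density (square-root)
  and maturity class; multiplicative lognormal noise (log-sd 0.15)
  represents destructive-sampling and biological variability.
- **Canopy cover**: cc = 1 − exp(−rate_c·AGB), with rate_c inversely
  proportional to the growth-period length (early cultivars spread more
  canopy per unit biomass). This cultivar-dependent coupling is the central
  realism choice: it makes spectral features ambiguous across maturity
  classes — the same cover maps to different biomass — which is precisely
  the ambiguity GPR exists to resolve. Without it the synthetic scene is
  trivially invertible from reflectance and the fusion comparison is
  uninformative.
- **Rasters**: 64×64 px per plot by default; a vegetation mask covering
  exactly the cover fraction (thresholded Gaussian-smoothed random field, so
  canopy forms clumps and texture carries spatial signal; i.i.d. placement
  available as a degenerate oracle), vegetation/soil endmember spectra
  (soil flat 0.22–0.30; vegetation red 0.05, NIR 0.50), additive Gaussian
  sensor noise (sd 0.01) clipped to [0, 1]. RGB is rendered from the
  red/green/blue reflectance slots.

What the generator does **not** emulate: radiometric calibration error,
orthomosaic stitching artifacts, shadows, soil-moisture variation, mixed
border pixels from imperfect plot digitization, plant-height structure, or
weather-driven growth setbacks. Passing tests therefore demonstrate that the
pipeline's algorithms are correct and that fusion helps under the stated
generative assumptions — not that any particular accuracy will be attained
on real imagery.

## Numerical and design choices

- All stochastic operations take explicit integer seeds; per-sample streams
  are spawned from `numpy` seed sequences, so regeneration is bit-identical
  and independent of iteration order.
- Scene rasters are written as plain multi-band TIFF (six float32
  reflectance bands, then RGB scaled to [0, 1]) with band metadata in the
  TIFF description tag; plot polygons as GeoJSON in pixel coordinates;
  weather, cultivar catalog and ground truth as CSV with ISO-8601 dates.
- Ties: Pearson ranking and VIF dropping break ties by feature name; the
  best-combo report ranks by test R² and breaks ties by lower test rRMSE.
- Degenerate inputs: constant GLCM patches quantize to a single level
  (features take their degenerate values, COR = 1); constant selection
  targets and empty polygon intersections are rejected with messages.
- Problem sizes in the test and acceptance suites (64–128 px rasters,
  50-iteration Boruta runs, five-seed repetitions) are chosen so the whole
  suite runs on a single CPU at desk scale while keeping every statistical
  check well-powered.

## Known limitations

- The six-band "panchromatic" slot participates in texture but no published
  index uses it; its endmember values are interpolations.
- The Otsu bimodality guard assumes roughly Gaussian within-class noise; a
  heavily skewed real-soil background could defeat the 3.2-separation
  heuristic.
- The repeated-holdout mode reuses the single-split machinery in a seed
  loop; no variance-corrected resampled t-tests are provided.
- GPR comes from calendar inputs only; the package does not infer phenology
  from imagery.
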