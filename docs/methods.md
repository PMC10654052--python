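# Methods

This note records the modelling choices behind `leaftypes`: what each
stage assumes, which tunable parameters matter, what the synthetic
landscapes do and do not emulate, and where the design was genuinely
open.

## The synthetic landscape

The generator is the package's substitute for the restricted global
inputs (inventory networks, trait databases, gridded covariates). Its
job is to provide a *known-truth* world with the statistical features
that make the downstream methods non-trivial, not realistic
climatology.

**Covariates.** Each layer is a Gaussian random field: white noise
smoothed with a Gaussian kernel (`correlation_length` pixels, wrapped
boundaries for stationarity), then standardized to mean 0, sd 1. Layers
combine a shared global field, a per-group field and an independent
field with weights √ρ_b, √(ρ_w − ρ_b), √(1 − ρ_w), where ρ_b is the
configured between-group correlation and ρ_w = 0.5 + 0.5 ρ_b the
within-group correlation — groups always cohere more internally than
across groups. Defaults: 28 layers (climate 10, soil 8, topography 7,
vegetation 3), so that the three big groups can each be reduced to six
principal components while vegetation passes through, matching the
structure of the driver analysis the pipeline implements; ρ_b = 0.3 as
a realistic climate–soil covariation.

A caveat that matters for interpretation: on a small grid the effective
number of independent spatial patches is roughly `rows·cols / (2π·L²)`
for correlation length L. At 32×32 with L = 4 that is ~10, so *any* 21
predictors are near-collinear by construction and a VIF < 4 screen must
fail — an artifact of desk scale, not of the method. The analysis
scripts therefore use 48×48 with L = 2.5 (~150 patches), where the VIF
screen behaves as it does on real ~1 km global grids.

**Truth surface.** Per pixel, broadleaf-vs-needleleaf log-odds are a
linear score of the designated *form* drivers and evergreen-vs-deciduous
log-odds of the *habit* drivers; the four class probabilities are the
products of the two margins (equivalently a softmax with additive
scores). This guarantees exact normalization and makes the two margins
independently controllable, so driver-recovery tests are unambiguous.
Defaults encode the structure the pipeline is meant to detect:
`climate_00` (cold-season-temperature analog) → form with coefficient
+2.0; `climate_01` (isothermality analog) +1.5 and `soil_00` (soil-pH
analog) −1.5 → habit. Coefficients are per standard deviation of the
(standardized) driver; ±1.5–2 spans compositions from near-pure to
mixed across a landscape, which is what global leaf-type maps look
like. `noise_scale` adds a smoothed Gaussian field to each log-odds;
the recovery tests use 0 ("signal only").

**Plots and traits.** Plot locations are uniform over pixels; tree
counts are 10 + Poisson(74) (mean ≈ 84, the mean plot size of the
inventory compilation the pipeline is designed for); leaf types are
multinomial draws from the pixel truth; DBH is lognormal
(meanlog 3.2, sdlog 0.45) left-truncated at 10 cm by inverse-CDF
sampling, giving a median adult stem of ~25 cm. Species pools are
disjoint across the four types (genera private to one type), so every
species' true type is unambiguous; the trait-catalog generator then
drops species entries at `missing_rate` (genus entries always survive,
exercising the fallback) and gives a `conflict_rate` fraction of
species multiple observations whose strict majority is still the truth.
Biomes are four latitudinal bands (tropical, arid, temperate, boreal,
south to north) standing in for biome polygons.

**What a green test does not establish.** The landscapes have no
anisotropy, no sampling bias toward accessible areas, no taxonomic
error, no trait observations that are *wrong* in the majority, and
covariates that are exactly the drivers plus correlated noise. Passing
recovery here shows the machinery is correct, not that real-world skill
will match.

## Inventory rules

Filtering is: latest survey year per plot id → drop stems with
DBH < 10 cm → drop plots with < 10 remaining adults → drop plots where
< 50% of adults resolve to a leaf type (counted per tree, not per basal
area). Compositions are computed over resolved trees only; an
"unknown" pseudo-class would leak the missingness mechanism into the
response. Modal trait resolution breaks ties by a fixed, configurable
priority (evergreen > deciduous, broadleaf > needleleaf); genus-level
types mirror the species rule one taxonomic level up. Plot area is
ignored throughout — compositions are unitless. Biome-proportional
downsampling keeps every tropical plot and subsamples biome *b* to
`round(n_tropical · share_b / share_tropical)` plots.

## Ensemble model

Training draws sample 10 individuals per plot **with replacement**
(weighted sampling without replacement is ill-defined when a plot has
exactly 10 trees). Members are scikit-learn `RandomForestClassifier`s
with `max_samples = 0.632`, probability output; note scikit-learn
averages per-tree class *probabilities* rather than counting hard
votes — the difference is immaterial for ensemble means and is absorbed
by the percentile CIs. Hyperparameter search runs on a single
representative draw (plot-level k-fold, pseudo-R² score, ties toward
fewer trees, then smaller mtry, then smaller node size); re-searching
per draw would multiply cost for no stated benefit. Covariates are
standardized with training-only statistics. Member seeds are spawned
from one `SeedSequence`, so the ensemble is reproducible and members
independent. CIs are 2.5–97.5 percentiles across members — bounded in
[0, 1] by construction, unlike mean ± 1.96 sd.

Models are persisted by *seed*, not by pickle: every training and
fitting seed is recorded in the pipeline manifest and a refit is
bit-identical, which keeps all artifacts text.

## Evaluation

`pseudo_r2` computes MAE_mean against the mean of the *scoring* set
(the pooled out-of-fold observations), keeping cross-validation honest
while matching the definition of the null model. Folds are assigned at
plot level so subsample draws of one plot can never straddle the
train/test split. Per-class R² is computed on pooled out-of-fold
predictions (not averaged over folds). Great-circle distances use the
haversine formula on a 6371.0088 km sphere; buffered LOO-CV skips (with
a warning) plots whose buffer leaves no training data. Semivariograms
are computed per composition class and averaged, since residuals are
4-vectors.

Known ceiling: with ~84-tree plots the observed compositions carry
multinomial noise that caps even the true-surface oracle near
R²_BC ≈ 0.93 on the 32×32 recovery world; fitted ensembles reach
≈ 0.88. Reported skill on synthetic worlds should be read against that
ceiling, not against 1.

## Drivers

Group PCA centers and scales before decomposition; groups with ≤ 6
members pass through (the vegetation treatment). VIF is the classic
1/(1 − R²) of each predictor on the rest, gate at 4. Importance models
are regression forests on the *area-based* evergreen share (habit) and
broadleaf share (form) — the natural plot-level reduction of the two
margins — over the sub-grid mtry 1–12 × node size 1–10, ranked by
out-of-bag R²; the ten best models' impurity importances are
normalized per model, then summarized by mean and 95% percentile CI.
Predictor columns are sorted internally so the ranking is exactly
invariant to caller column order. Group-level summaries *sum* the six
PC importances per group (the aggregation was ambiguous; sum preserves
the "share of total importance" reading). The convex-hull diagnostic
projects prediction points with the training PCA (training centering,
scaling, eigenvectors — never refit), tests each C(n,2) PC pair's hull
with boundary counted as inside, and summarizes the fraction of points
inside ≥ 90% of hulls.

## Accounting and climate risk

Cover renormalization divides each forest-type fraction by the total
forest fraction (idempotent, scale-invariant). Density partitioning
uses individual-based compositions (stems are counts), biomass uses
area-based (large stems hold the carbon); absolute biomass per pixel is
density × canopy cover × pixel area with spherical cosine-of-latitude
pixel areas on a 6371.0088 km sphere. Totals are conserved exactly by
construction and asserted to 1e-6 relative.

Forest-type labels require a *strict* majority above the threshold
(share = 0.60 → mixed, since the definition is "> 60%"); thresholds
≤ 0.25 are rejected as two classes could tie above them. Future
projections verify that only climate-group layers changed, average
ensemble members within each climate model, then average climate
models. "Forested" means canopy cover > 0 in the supplied cover
raster. The risk summary is a *climate-envelope* screen: it identifies
where future climate matches conditions that currently support a
different type, and explicitly does not project actual vegetation
change.

## Numerical choices and degenerate inputs

- Compositions validate to a 1e-9 sum tolerance; truth surfaces are
  renormalized exactly after the softmax.
- BC is clipped at 1 to absorb floating-point overshoot for identical
  vectors.
- Zero-variance classes yield NaN per-class R² with a warning, never an
  exception; single-class training sets fit with a warning and predict
  that class everywhere.
- Degenerate (collinear) hull point sets count as "not covering" with
  a warning.
- Every stochastic operation takes an explicit integer seed;
  ensemble-member and pipeline-stage seeds are spawned from
  `numpy.random.SeedSequence`.

## Limitations

- Desk-scale grids: all defaults target minutes on one CPU; the
  recovery ensemble uses 10 draws (not 100) — CI widths are therefore
  illustrative, not calibrated to the 100-member design.
- The synthetic biome bands make biome aggregation exercisable but
  carry no ecological content.
- No taxonomic name standardization: the resolver hook is identity;
  real trait tables need external cleaning first.
- NetCDF (scipy backend) replaces GeoTIFF throughout; consumers needing
  GeoTIFF can convert with any GDAL tool.
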