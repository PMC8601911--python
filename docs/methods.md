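# Methods

This note documents the models, conventions and design choices behind
`grassnet`, in the order the pipeline runs them.

## Observation model

Surveys follow a removal protocol: a 10-minute point count is divided into
J = 5 two-minute bins and only newly detected individuals are recorded, so
an individual present at site *i* lands in bin *j* with probability
π_ij = p_i(1−p_i)^{j−1} and is missed entirely with probability (1−p_i)^J.
The per-bin detection probability p_i follows a logit-linear model in
standardized Julian date. Counts are of singing males, so all densities are
effectively singing-male densities.

Latent abundance is N_i ~ Poisson(λ_i·A), log λ_i = x_iᵀβ with standardized
land-cover and climate covariates. The offset A is the area of a 100-m
radius circle (π·0.1² ≈ 0.0314 km²), matching the covariate-buffer radius,
so λ is a density per km². The survey protocol restricts counts to the
0–50 m distance bin while the offset uses the 100-m buffer area; the
package treats `offset_area_km2` as the effective sampled area and does not
resolve that mismatch — change the offset if a different effective area is
defensible.

Marginalizing N gives the closed form used everywhere in production: the
total T_i = Σ_j y_ij is Poisson with mean λ_i·A·q_i, q_i = 1−(1−p_i)^J,
and the bin split is conditionally multinomial with probabilities π_ij/q_i.
A brute-force truncated sum over N is kept in the test suite as an
independent oracle; the two agree to < 1e−8 over a grid of small cases
(the float error is ~1e−14).

## Fitting and inference

* Maximum likelihood by BFGS from a zero start with the analytic gradient;
  one deterministic restart from a perturbed start on failure; gradient
  tolerance 1e−6, max 500 iterations. Non-convergence is returned as a
  flag, never silently.
* Covariance = inverse of the observed information, computed by central
  finite differences of the analytic gradient (step 1e−5, symmetrized). A
  singular information matrix raises.
* Goodness of fit: Pearson chi-square over site × interval cells
  (expectations λ̂Aπ̂_ij, floored at 1e−4 to avoid division blow-ups),
  referenced to a parametric bootstrap (simulate from the fitted model,
  refit, recompute). ĉ = observed/mean(bootstrap); p = fraction of
  bootstrap values ≥ observed. ĉ is floored at 1; standard errors are
  multiplied by √ĉ, widening all Wald intervals while leaving point
  estimates unchanged.
* Validation: repeated 70/30 holdouts scoring AUC of the detection
  indicator against 1−exp(−λ̂Aq̂) (detection-based, a documented choice —
  the probability could equally be defined through occupancy), RMSE/MAE of
  expected totals (the holdout metric is a package choice and labeled as
  such), Spearman's ρ between observed and expected totals, and a binned
  Moran's I correlogram of Pearson residuals (uncentered pair products,
  distance bins to 30 km, 100-permutation 95% envelope). "No residual
  autocorrelation" means the observed I stays inside the envelope. A
  spline-smoothed correlogram would be presentation polish only; the binned
  version preserves the envelope criterion.

### Compositional covariates

On a fully labeled four-class mosaic the land-cover proportions sum to one
in every buffer, so the four standardized proportions plus an intercept are
exactly collinear and the model is unidentifiable. Real land-cover products
escape this only because they carry extra classes (water, wetland, barren).
Analyses on `grassnet`'s synthetic rasters should therefore drop one cover
class as the reference; the bundled demo fits grassland, forest, urban,
tmax and prcp with agriculture as the complement. `ModelSpec` itself is
agnostic: any subset of named covariates (including none, for an
intercept-only model) is valid.

## Prediction surfaces

Each 1-km² cell's covariates are standardized with the *fitting* scaling
parameters (means and sample n−1 SDs, stored on the model) and pushed
through exp(xᵀβ̂). Error propagation shifts all abundance coefficients
jointly by ±1.96·SE (ĉ-adjusted, covariances ignored) — deliberately
faithful to the common practice it reproduces rather than statistically
elegant; no ordering among the three layers is guaranteed where
standardized covariates are negative. Linear predictors are clipped at
±700 before exponentiation so extreme extrapolation stays finite. All
downstream evaluations run independently per layer.

Population in a cell is density × 1 km²; "statewide population" is the sum
over cells.

## Conservation evaluation

* **Baseline density**: mean over cells whose centers lie within the area
  polygon dilated by 500 m (inclusive distance), so the ring of
  edge-adjacent 1-km cells is included but diagonal corners (707 m) are
  not. Whether the original buffer rule meant polygon intersection or cell
  centers is ambiguous; center-distance dilation is the reproducible
  analogue on a cell-mask representation. Replicate areas use a zero
  buffer — the buffer exists to catch boundary-straddling pixels of the
  real, polygon-defined areas.
* **Percent of statewide population** counts overlapping footprint cells
  once and is compared to the 20% planning target and the 10% IUCN
  critically-endangered threshold.
* **Minimum set**: cells sorted by density descending (ties broken
  row-major) and accumulated until the target fraction is reached — exact
  for this objective, verified against exhaustive search on ≤12-cell
  instances. A 1e−12 relative tolerance on the cumulative comparison keeps
  exact-fraction cases (uniform surfaces) at ⌈target·n⌉ cells.

## RTR null model

A replicate is the source footprint's cell-union polygon rotated by
Uniform(0, 2π) about its centroid, translated uniformly over offsets that
keep it inside the sampling region, and re-rasterized by cell-center
containment. Conventions and constraints:

* Accepted poses must lie entirely within the region (not merely their
  centroids), keep the rasterized cell count within ±5% of the source
  (rasterization tolerance, configurable), and — at the replicate level —
  contain at most 20% unsuitable cells, where a cell is unsuitable when
  forest + urban cover ≥ 50%. Rejected replicates are redrawn; rejection
  tallies are reported.
* GBCA-ensemble replicates place members sequentially, redrawing any member
  that overlaps an earlier one; the unsuitable-habitat cap applies to the
  ensemble union.
* Replicates may overlap one another and the real conservation area —
  excluding the real area would bias the null upward.
* Representation: baseline strictly greater than the empirical 90th
  percentile (linear-interpolation sample quantile) of the replicate
  means — a one-sided "top 10% of the null" rule whose type-I error on an
  exchangeable landscape is ≈10% (verified at 7–13% over 500 trials).
* Within a scenario the 1000 placements per area are shared across species
  (same geometry, different surfaces), removing between-species Monte-Carlo
  noise; per-area placements come from independent substreams of the
  scenario seed. Attempt caps: 1000 proposals per accepted replicate, 10⁶
  globally, with informative failures.

## Synthetic data generator

The generator emulates the inputs of a statewide citizen-science abundance
analysis; every default is a study condition, not a tuning knob.

* **Land cover**: two independent Gaussian fields smoothed to the
  configured autocorrelation range (default 2 km) are rank-split so realized
  class counts match the target fractions (default 40/30/20/10
  grass/agriculture/forest/urban — a grass-rich working landscape) up to
  integer rounding, at any seed. The mosaic has realistic patchiness but
  not real-world geometry: no roads, rivers, or class-adjacency structure.
* **Climate**: mean + linear trend + smoothed noise; defaults approximate
  upper-Midwest May–July normals (tmax 28 °C ± small trend, precipitation
  320 mm). An optional Gaussian warm bump can be centered on a focal
  landscape to build a species with a known concentration.
* **Network**: rectangular-block footprints placed by rejection sampling in
  grass-rich (mean grassland ≥ 0.30) and suitable (≤20% unsuitable cells)
  locations; GBCAs nested, disjoint. Real conservation areas have irregular
  boundaries; block shapes are deliberately simple — the RTR machinery is
  shape-agnostic (it rotates arbitrary cell unions).
* **Surveys**: uniform site locations with >400-m spacing via bounded
  rejection sampling (explicit error on infeasibility), survey dates
  uniform over days 152–196 (the passerine breeding window).
* **Counts**: N ~ Poisson, then a multinomial split over the J bins and the
  miss cell — the exact data-generating process the model assumes. The
  generator works directly at the 2-min-bin level (the model sees only
  bins). Passing tests on these data show the chain is *self-consistent*;
  they cannot show robustness to real-data violations (observer
  heterogeneity, double counting, within-survey movement, distance
  misclassification).
* **Seeding**: one master seed spawns independent child streams per
  generator, so stages are reproducible in isolation.

## Problem sizes in the bundled studies

The demo landscape is 100 × 100 km (50-m land-cover cells, 1-km²
prediction grid, 10,000 cells), three 196-km² focal landscapes with three
9-km² GBCAs each, 600 survey sites, 50 bootstrap GOF replicates and 1000
RTR replicates per area — a deliberate ~1/13-scale version of a statewide
analysis that keeps a full run in tens of seconds. The recovery and
calibration studies use 300 sites and a truth of ~20 birds/km² at mean
covariates (~180 detections per dataset), chosen so Monte-Carlo error, not
finite-sample MLE bias, dominates at that size; 50 replicate datasets for
recovery/coverage and 20 for ĉ calibration.

## Known limitations

* Detection probability is constant across bins within a survey (the
  standard removal assumption); time-varying p is not modeled.
* Single-species models only; no spatial random effects (residual
  autocorrelation is tested, not modeled); no distance-sampling component;
  no model selection or averaging.
* The minimum-set planner optimizes a single species' population target —
  it is not a complementarity-based multi-species reserve design.
* The ±1.96·SE layers ignore coefficient covariances by construction.
* The RTR null assumes the density surface is exchangeable over suitable
  habitat at the footprint scale; strong statewide gradients make the null
  conservative for areas sitting on a gradient's high end.
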