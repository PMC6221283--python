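# Methods

This note documents the models implemented in `nicheshift`, the defaults
and why they were chosen, what the synthetic scenarios do and do not
emulate, and the numerical choices that affect results.

## Maximum-entropy distribution model

The model (`nicheshift.maxent`) is the presence-background maximum-entropy
estimator: among all distributions over the background cells whose feature
expectations match the presence sample, it selects the one of maximum
entropy — equivalently the Gibbs density `q_λ(x) ∝ exp(λ·f(x))` maximizing
the L1-penalized presence log-likelihood. Assumptions worth keeping in
mind:

- presences are an unbiased (if thinned) sample of where the species
  occurs, and the background characterizes what is available;
- the species' response is captured by linear, quadratic and product
  terms of the scaled predictors. Hinge and threshold features are not
  representable at all, a deliberate restriction that trades flexibility
  for smooth, interpretable response curves;
- background points serve as pseudo-absences for threshold-based
  evaluation (TSS); this is the standard presence-background
  approximation and inflates neither AUC's nor TSS's ranking role, but
  absolute values are not comparable with true presence-absence studies.

### Features and regularization

Each predictor is min-max scaled to [0, 1] using its training bounds;
squares and pairwise products of the scaled values complete the feature
set (d + d + d(d−1)/2 columns for d predictors). On projection, values
outside the training bounds are clamped by default — era-shifted climates
routinely step outside the calibration range, and unclamped polynomial
features extrapolate wildly.

The per-feature penalty is `β_j = c · tab_class(m) · s_j / √m` where `m`
is the presence count, `s_j` the feature's standard deviation over the
presences, `tab_class` the published per-class default tables
(interpolated in m; linear features are penalized least, products most at
small samples), and `c` the single user-facing multiplier (default 1.0).
`s_j` is floored at 1e-3 so a feature that happens to be constant over
the presences but varies over the background cannot enter the model
unpenalized; features constant over both are frozen at zero.

### Optimization

Proximal gradient ascent with backtracking line search and soft
thresholding for the L1 term. The objective trajectory is stored on the
model and is non-decreasing by construction (tests assert this on every
fit). Convergence is declared when the objective improves by less than
`tol` (default 1e-6, on a log-likelihood scale of order log(background
size) ≈ 7–9; tightening to 1e-8 changes predictions at the ~1e-6 level
while roughly doubling iteration counts). Default iteration cap 5000.
Non-convergence raises an error carrying the objective path.

### Outputs and evaluation

`raw` sums to exactly 1 over the training background (the normalizer is
recomputed after convergence). The default reporting transform is
cloglog, `1 − exp(−e^H · raw)` with H the entropy of the training raw
distribution — the modern MaxEnt-era default; logistic and raw are
selectable. All transforms are strictly monotone, so AUC is identical
under any of them.

Evaluation uses a seeded 70/30 shuffle split of the (per-pixel thinned)
presences. AUC is the Mann–Whitney statistic (ties half-weighted),
computed via the ROC curve; TSS is reported at the threshold maximizing
sensitivity + specificity, a rule chosen because it needs no prevalence
assumption — the threshold rule is configurable. Both train and test AUC
are written by the pipeline. Degenerate (constant-score) evaluations
return AUC 0.5 / TSS 0 and are flagged rather than raised.

### Collinearity filter and sample-size guard

Predictors are filtered before fitting: while any pair has |r| ≥ 0.95
over the off-nodata cells, the member of the worst pair with the larger
mean absolute correlation to the remaining predictors is dropped. The
over-parameterization guard requires at least ten presences per kept
predictor and is reported as a flag (`guard_ok`) rather than enforced,
since the appropriate reaction (drop variables, pool records) is a study
decision.

## Environmental ordination and overlap

`nicheshift.niche_space` ordinates the background environment with a
correlation-matrix PCA (z-scored variables, eigendecomposition of the
correlation matrix, deterministic sign convention: the largest-magnitude
loading on each axis is positive). Niches are compared in the plane of
the first two axes, gridded at R×R cells over the min/max of the
background scores — the envelope of conditions present in the study
area. R defaults to 100, the established convention for this framework.

Occurrence and availability densities are Gaussian product-kernel
estimates evaluated at the cell centers. Bandwidths follow Silverman's
rule per axis on the point set at hand, floored at one grid cell so the
kernel never collapses below the grid resolution at small sample sizes.
The occupancy grid divided by availability (defined as 0 where
availability is 0) corrects for unevenly available conditions; both
corrected (default) and uncorrected variants are computed and either can
feed Schoener's D, since which variant older studies used is often
ambiguous. D normalizes each grid to sum 1 internally, so it is invariant
to positive rescaling; D is symmetric and lies in [0, 1] up to floating
point.

## Permutation tests

Both tests (`nicheshift.overlap`) use the add-one rank p-value
`(r+1)/(n_reps+1)` with ties counted in the rejection tail — the only
formula consistent with a p-floor of 1/(n_reps+1) and never zero. The
default of 100 replicates gives a floor of 1/101 ≈ 0.0099; raise
`n_reps` for sharper floors.

- **Equivalency**: all occurrence scores are pooled, shuffled and split
  back into the original sample sizes; both grids are rebuilt (each
  against its own background, bandwidths re-estimated per replicate, the
  availability density precomputed once) and D recomputed. Lower-tail
  test; verdict "Not Equivalent" at α = 0.05.
- **Similarity (directional, a→b)**: the observed smoothed density of
  taxon b is translated by whole grid cells so its centroid lands on a
  uniform random point of b's background envelope; mass shifted off the
  extent is truncated (the truncated fraction is recorded per replicate)
  and the grid renormalized inside D. Upper-tail test; verdict "Similar"
  at α = 0.05. Translating the density rather than resampling points
  around the shifted centroid is an interpretation choice: it is cheap,
  deterministic given the draw, and preserves the niche's shape exactly.

Under exchangeable inputs the equivalency p-value is exactly
discrete-uniform on k/(n_reps+1); the test suite verifies this by a KS
test against that discrete CDF over 200 independent runs.

## Synthetic scenarios

The generator (`nicheshift.synthetic`) emulates the structure of a
bioclimatic niche study, not its physics:

- **Layers** are unit-variance Gaussian random fields (white noise
  convolved with a Gaussian kernel of scale `autocorr_length`, default 8
  cells) mixed by a factor of a target cross-correlation matrix. The
  seven default layer names follow the classic bioclim selection (annual
  mean temperature, temperature seasonality, coldest-month minimum,
  annual range, annual precipitation, precipitation seasonality,
  driest-quarter precipitation). `bioclim_block_correlation()` provides
  a realistic structure — temperature variables inter-correlated 0.7,
  precipitation variables 0.7, the blocks at −0.4 — which puts the main
  temperature-vs-precipitation gradient on the leading PCA axis, as in
  real data. The `ScenarioConfig` default is the identity matrix
  (neutral); note that with fully independent layers the two-axis PCA
  plane is rotation-degenerate, so scenarios intended for niche
  comparison should use correlated layers.
- **Eras** are additive per-layer offsets; no change in spatial pattern,
  no physics. Offsets are free scenario parameters.
- **Soils** are an independent autocorrelated field thresholded at the
  quantile giving the requested cover. The default `soil_fraction` of
  0.061 mirrors the share of gypsum outcrops in the semi-arid peninsula
  this emulates.
- **Occurrences** are drawn at cell centers without replacement with
  probability ∝ suitability × soil mask, matching the one-record-per-
  pixel thinning applied to real data. Ground truth is a logistic
  linear+quadratic response on z-scored layers.

What passing tests on these scenarios shows: the chain recovers known
suitability rankings (Spearman ≥ 0.8 at 500 presences on a 100×100
landscape), its permutation tests are calibrated, and its outputs are
deterministic. What it does not show: robustness to sampling bias,
spatial autocorrelation of *occurrence effort*, nodata geometry, climate
non-stationarity, or predictor measurement error — none of which the
generator emulates.

## Raster and occurrence conventions

ESRI ASCII grids with corner registration only (`xllcorner`); the
cell-center dialect is rejected explicitly rather than silently
reinterpreted. Row 0 is the northernmost row in memory, matching the
file layout. A point belongs to exactly one cell via half-open cell
intervals; per-pixel thinning keeps the first-seen record, so results
are deterministic given input order. Nodata is NaN in memory and a
sentinel (default −9999) on disk; values are written at full float
precision so write→read round-trips are exact.

## Pipeline determinism and problem sizes

One master seed is fanned out per stage/taxon/pair by hashing the stage
name (SHA-256, reduced below 2^31), so any stage can be rerun in
isolation and a full rerun is byte-identical in every numeric output
(the run log carries wall-clock timestamps and is excluded). Boxplot
summaries use type-7 (linear-interpolation) quantiles and Tukey 1.5·IQR
whiskers, stated in the output metadata.

The test suite exercises the chain at 60×60–100×100 grids, 50–500
occurrences, R = 40–100 and 25–100 permutation replicates; these sizes
are the package's reference conditions for its statistical checks and
complete in well under a minute each.

## Known limitations

- No GeoTIFF/netCDF input, no reprojection; geographic degrees are taken
  at face value (no equal-area correction of cell weights).
- Exact parity with the Java MaxEnt 3.4.1 program is not attempted; the
  estimator is the same family (L1-regularized Gibbs over background,
  LQP features) but feature scaling details and optimizer paths differ.
- The similarity-test null translates densities; alternatives that
  resample occurrences around shifted centroids would give slightly
  different nulls.
- No multiple-testing correction across taxon pairs; apply your own if
  you test many pairs.
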