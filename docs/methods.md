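# Methods

This note documents the models, parameter choices, numerical details
and known limitations of the `richdet` pipeline.

## The analysis model

The response is per-unit species richness R. Throughout, richness,
county area and strictly positive covariates are analyzed on the
log10 scale; temperature-level variables stored in 0.1 °C (which drop
below zero in cold regions) and the categorical land-cover code pass
through untransformed, and the decision made for each variable is
recorded in every report. The area effect is removed first:
log10 R is regressed on intercept + log10 area by OLS and the
residuals form the analysis response, so that larger counties do not
masquerade as richer ones. An alternative treatment (area as a model
covariate on the raw response) is implemented in
`area_effect_check`, which reports both importance rankings and flags
disagreement.

### Screening (step 1)

Covariates belong to five hypothesis categories: water–energy
dynamics, ambient energy, productivity, environmental stability and
habitat heterogeneity. Within each category, while any pair exceeds
|Spearman ρ| > 0.7 (two-sided, average ranks for ties), the pair with
the largest |ρ| is resolved by dropping the member whose univariate
Gaussian regression on the residual response explains less deviance
(equivalently, lower r²). Ties in deviance break lexicographically by
name, making the procedure fully deterministic; permuting column
order does not change the retained set when the statistics are
distinct. Cross-category correlations are deliberately left alone —
the screen reduces redundancy *within* a hypothesis, not between
competing hypotheses. The univariate deviance is computed against the
area-residualized response, matching the step order of the pipeline.

### Bootstrap selection (step 2)

The Gaussian-identity GLM (OLS with t-based p-values) of the residual
response on the screened covariates is refitted on `reps = 1000` case
resamples of the n units drawn with replacement; a variable's count
increments when its coefficient attains p < `alpha = 0.05`. The six
(`k = 6`) variables with the highest counts are selected; boundary
ties break by larger mean |t| across replicates, then name, and every
tie decision is logged. Rank-deficient resamples are redrawn (logged,
capped at 10× reps).

A calibration caveat worth stating plainly: because all replicates
share one dataset, per-variable counts are *not* Binomial(reps, α)
under the null — the resampled t-statistic is approximately the
observed t plus unit noise, giving a marginal null significance rate
near 0.17 rather than 0.05, and counts that are strongly
over-dispersed across datasets. The procedure is used for what it is
good at: *ranking* predictors by the stability of their significance,
which it does reliably (a standardized effect ≥ 0.12 at n = 2000 is
selected into the top six essentially always, see the acceptance
tests). The 5% calibration of the underlying p < 0.05 decision holds
in the textbook sense — across independent datasets — and is verified
that way.

### Spatial-error regression (step 3)

Residual spatial autocorrelation is modelled with a simultaneous
autoregressive error: y = Xβ + u, u = λWu + ε, ε ~ N(0, σ²I). W is a
row-standardized distance-band adjacency on planar centroid
coordinates in km: i ~ j iff 0 < d(i,j) ≤ lag. Units with no neighbor
keep zero rows (OLS-like behavior), are excluded from S0, and their
fraction is reported because it affects comparability across lags.
Candidate lags are {50, 100, 200, 400, 600, 800, 1000} km and the
minimum-AIC lag is chosen per fitted model.

Estimation maximizes the concentrated log-likelihood

ℓ(λ) = −(n/2)(ln 2π + ln σ̂²(λ) + 1) + Σᵢ ln(1 − λeᵢ),

where β̂(λ) is the GLS fit of (I − λW)y on (I − λW)X, σ̂²(λ) the
mean squared filtered residual, and eᵢ the eigenvalues of W —
computed once per weights object through the symmetric similarity
D^(−1/2)AD^(−1/2), which guarantees they are real for distance-band
weights. The 1-D search is bounded Brent over the stationarity
interval (1/min eᵢ, 1/max eᵢ) with tolerance 1e−8. Coefficient SEs
default to the GLS covariance σ̂²(X′A′AX)⁻¹ at λ̂; a numerical-Hessian
route over (λ, β, ln σ²) is kept for cross-validation and agrees with
the GLS route to ~15% in simulations. AIC counts p + 2 parameters
(all coefficients including the intercept, plus λ and σ²).

Model fit is summarized by a pseudo-r²: the squared Pearson
correlation between observed y and predicted
ŷ = Xβ̂ + λ̂W(y − Xβ̂). The prediction includes the spatial signal
term by default (a trend-only variant is exposed as an option).
Residual autocorrelation is diagnosed with Moran's I of the
innovation residuals (I − λ̂W)(y − Xβ̂) — the quantity the model
claims to whiten. The Δr² robustness check fits the top-6 and
all-variable models at the same lag and reports r²(all) − r²(top6)
with both AICs; because log10(dryness) = log10(MAP) − log10(PET)
exactly, the all-variable design carries one exact linear dependency,
and a maximal independent column subset (sequential projection with
protected top-6 columns) is used, with dropped columns reported.

### Moran's I

I = (n/S0) Σᵢⱼ wᵢⱼzᵢzⱼ / Σᵢzᵢ² on centered values, with a permutation
p-value: two-sided against the permutation distribution, centered at
the exchangeability expectation E[I] = −1/(n − 1), with the +1
continuity correction, default 999 permutations.

### Split-line regression

Units with predictor values above a cap (default 6,000 m for
elevational range) are excluded; for each candidate breakpoint the
two sides are fitted by *independent* OLS lines (a discontinuity is
allowed — the two-regime report of per-segment R², F and p arises
naturally from independent fits; a continuity-constrained hinge is
not the default). Points exactly at the breakpoint go to the lower
segment. The candidate minimizing total RSS wins; ties prefer the
smaller breakpoint; candidates leaving fewer than four points on a
side are inadmissible. The default grid is every 50 m from the 5th to
95th percentile of the capped predictor. Resolution honesty: with
noise at 25% of the pre-segment response range and n = 1000 the
breakpoint's sampling SD is ~150 m, so recovery "to one grid step" is
a meaningful claim at a ~250 m grid, not at 50 m; the noiseless case
is exact on any grid containing the true break.

### Robustness and completeness

The sampling-bias test draws, per replicate, a stratified subsample
*without* replacement — ⌊fraction · n_s⌋ units (≥ 1) per stratum — at
fractions {0.6, 0.7, 0.8, 0.9}, refits the GLM, counts significance
as in step 2, and compares each fraction's top-6 set with the
full-data set; the consistency flag is true iff all sets match. The
full-data reference is the step-2 case-resampling bootstrap itself,
so a fraction of exactly 1.0 reproduces its counts for the same seed.
The two resampling schemes (with replacement in step 2, without in
the robustness test) are intentional and kept distinct.

The completeness audit restricts to units whose incompleteness score
exceeds 0.05, and reports the mean and SD of the richness difference
(analysis inventory − reference) plus higher/identical/lower counts;
the nested-reserve comparison is a plain Pearson correlation with
two-sided p between paired county and reserve richness. The
incompleteness score itself is treated as an opaque per-unit input.

## The synthetic landscape generator

The generator emulates the structure of a national county-level
richness dataset so that every analysis stage has a testable ground
truth.

- **Units.** 2,376 counties by default, split 1995/210/171 across
  three rectangular regions (a large humid "EMR", an arid "NAR", a
  high-plateau "QTR") in a 4000 × 3000 km planar domain; centroids
  uniform per region. Planar km coordinates are used throughout — no
  geodesy, so Euclidean distance is exact by construction.
- **Areas.** Lognormal with mean 3908.7 km² and SD 9287.6 km²,
  drawn as randomly permuted mid-grid quantiles rather than iid:
  with CV ≈ 2.4 the iid sample SD is extremely noisy, while the
  low-discrepancy draw keeps realized moments within a few percent
  deterministically (the SD carries a small systematic ~8% tail
  truncation at n = 2000).
- **Covariates.** Each of 19 named variables starts as white noise
  filtered through (I − ρW)⁻¹ (ρ = 0.7 by default; W at the 200 km
  band), is rescaled per region to tabulated mean/SD targets, and
  strictly positive variables are floored at 1% of the regional
  target mean so the log10 transform stays defined (negligible for
  variables whose mean exceeds ~2 SD; noticeable only for the
  driest-quarter precipitation in the arid region, which is not a
  calibration target). Configured cross-correlations — by default
  NDVI with precipitation at r = 0.77 inside the arid region — are
  induced by empirical factor mixing (orthogonalized shared factor),
  so the realized correlation equals the target exactly before the
  positivity floor. Dryness is derived as MAP/PET rather than drawn
  (meaning it is *exactly* log-collinear with its parents — see the
  Δr² note above). The land-cover code is a quantile-thresholded
  latent field with 10 classes, entering regression as its integer
  code since the analysis reports a single z for it.
- **Richness.** log10 R = intercept + Σβₖxₖ + γ·log10 area + u with
  u = λWu + ε. Defaults: β = {elevational range 0.45, NPP 0.25,
  precipitation 0.15, precipitation seasonality −0.10} on the
  analysis scale, γ = 0.2, λ = 0.6, σ = 0.18, intercept −0.30 —
  chosen once so that the median county holds ~350 species, most
  units fall below ~400 and the maximum is of order 3×10³,
  mirroring the magnitude structure of real national inventories.
  σ = 0 is allowed for noiseless closed-form checks. An optional
  breakpoint replaces one variable's linear term with a two-slope
  hinge on the raw scale.
- **Degraded surveys.** Binomial thinning: observed ~
  Binomial(true, 1 − rate), with the realized omitted fraction as the
  per-unit incompleteness score — simple, monotone in the omission
  rate in expectation, and sufficient to exercise the audit.
- **Pixel raster.** A smoothed random elevation surface (non-negative
  by rescaling) and a thresholded land-cover surface on a regular
  grid, assigned to counties by nearest centroid, with each centroid
  contributing its own cell so no county is empty; zonal statistics
  (mean, max−min range, modal class with smallest-class tie-break)
  reproduce how county-level covariates are derived from rasters.

What the generator does *not* emulate: real spatial anisotropy and
coastlines, raster-derived covariate error, taxon-level occurrence
processes (richness counts only), non-stationary covariate effects,
and observation error beyond binomial thinning. Passing tests
therefore demonstrate the *procedures* are correct and well-calibrated
under the model's own assumptions, not that those assumptions hold
for any particular real dataset.

## Reproducibility and problem sizes

All randomness descends from named integer seeds through
`numpy.random.SeedSequence`; repeated runs are bit-identical, and the
pipeline's JSON reports (sorted keys, no timestamps) are byte-equal
across runs with the same seed. Simulation-based checks use problem
sizes chosen to make their Monte-Carlo error small relative to the
tolerance being asserted: λ-recovery uses 200 landscapes of n = 400;
the OLS-limit check averages λ̂ over 30 independent n = 1000 datasets
(a single λ̂ has sampling SD ≈ 0.03–0.05, so no single fit can be
asserted to ±0.02); selection and robustness rates use n = 2000
designs with 200 replicates per run across 10–20 independent runs.

## Known limitations

- Eigenvalues of W are computed densely (O(n³)); comfortable to a few
  thousand units, not for n ≫ 10⁴.
- The SAR implementation covers the error form only — no lag or mixed
  variants, no spatial filtering, no Bayesian estimation.
- Breakpoint inference reports per-segment F tests, not a formal
  breakpoint-existence test; multi-breakpoint segmentation is out of
  scope.
- k-nearest-neighbor and polygon-contiguity weights are not
  implemented; distances are centroid-to-centroid.
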