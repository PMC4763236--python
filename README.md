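# richdet — determinants of county-level species richness

`richdet` implements a complete macroecological analysis pipeline for
asking *which environmental factors control species richness* across a
set of assessment units (counties), nationally and within
climatically distinct regions. It is aimed at biodiversity and
macroecology researchers who have a per-unit richness inventory plus
environmental covariates, and want a reproducible, spatially honest
determinants analysis rather than a naive multiple regression.

The pipeline follows a three-step design used in county-level richness
studies:

1. **Screening.** Richness, area and strictly positive covariates are
   log10-transformed; richness is residualized on county area by OLS.
   Within each of five hypothesis categories (water–energy dynamics,
   ambient energy, productivity, environmental stability, habitat
   heterogeneity), covariate pairs with |Spearman ρ| > 0.7 are pruned,
   keeping the member that explains more deviance in a univariate
   Gaussian regression.
2. **Bootstrap selection.** A Gaussian GLM of the residual response on
   the screened covariates is refitted on 1000 case resamples; each
   replicate counts a variable as significant when its coefficient has
   p < 0.05. The six most frequently significant variables are kept.
3. **Spatial-error regression.** The top-6 model is refitted as a
   simultaneous autoregressive (SAR) error model,

   y = Xβ + u,  u = λWu + ε,  ε ~ N(0, σ²I),

   with W row-standardized distance-band weights. Candidate band
   radii {50, 100, 200, 400, 600, 800, 1000} km are compared by AIC.
   Estimation is maximum likelihood: the concentrated log-likelihood
   ℓ(λ) = −(n/2)(ln 2π + ln σ̂²(λ) + 1) + Σᵢ ln(1 − λeᵢ) is maximized
   over λ (eᵢ the eigenvalues of W), with β̂(λ) by GLS. Predictors are
   ranked by z = β̂/SE; model fit is a pseudo-r² (squared Pearson
   correlation of predicted and observed, prediction including the
   spatial signal λ̂W(y − Xβ̂)); residual spatial structure is
   diagnosed with Moran's I; and a Δr² against the all-variable model
   checks that the six predictors suffice.

Around that core the package provides split-line (breakpoint)
regression of richness on elevational range with a 6,000 m exclusion
cap, a stratified-subsample robustness test of the top-6 set at
60–90% sampling fractions, inventory-completeness audits, a hotspot
(richest 5%) utility, and a **synthetic county-landscape generator**
that reproduces the statistical structure such analyses assume —
three regions with calibrated covariate moments, spatially
autocorrelated fields, an NDVI–precipitation correlation of 0.77 in
the arid region, lognormal county areas (mean 3908.7 km², SD 9287.6
km²), a SAR(λ)-correlated richness error, and binomially thinned
"survey" inventories — so every stage is testable end to end without
any external data.

## Worked example

```python
import numpy as np
from richdet import (
    GeneratorConfig, generate_counties, generate_env_fields,
    generate_richness, build_distance_band_weights,
    residualize_on_area, screen_variables, bootstrap_significance,
    select_top_k, select_lag, log_transform,
)

cfg = GeneratorConfig(n_units=800, seed=3)
counties = generate_counties(cfg)
w = build_distance_band_weights(
    counties[["x_km", "y_km"]].to_numpy(), cfg.spatial_range_km,
    ids=counties["id"].to_numpy(),
)
env = generate_env_fields(counties, cfg, w)
rich = generate_richness(counties, env, w, cfg)

y = residualize_on_area(np.log10(rich), np.log10(counties["area_km2"]))
screened = screen_variables(env, y)
x, _ = log_transform(env)
report = bootstrap_significance(y, x[screened.retained_names], reps=1000, seed=0)
top6 = select_top_k(report, k=6)
best_lag, table, fits = select_lag(
    y, x[top6], counties[["x_km", "y_km"]].to_numpy(), candidate_lags=(100.0, 200.0, 400.0),
)
fit = fits[best_lag]
print(best_lag, round(fit.lam, 2), {v: round(fit.z[v], 1) for v in top6})
```

prints

```
200.0 0.61 {'elevational_range': 42.6, 'net_primary_productivity': 13.9,
 'mean_annual_dryness': 5.9, 'ndvi': -1.8, 'mean_annual_temperature': 1.0,
 'precipitation_seasonality': -2.5}
```

i.e. the 200 km band minimizes AIC, the spatial-error coefficient λ̂ ≈
0.61 recovers the generating autocorrelation (λ = 0.6), and elevational range —
the habitat-heterogeneity proxy the generator makes dominant — attains
by far the largest z, followed by productivity and water variables,
with the remaining predictors indistinguishable from noise.

The same analysis is available as a narrative sequence of drivers:

```sh
python analysis/01_generate_landscape.py      # synthetic counties + covariates
python analysis/02_screen_variables.py        # step 1 per region
python analysis/03_select_predictors.py       # step 2: bootstrap top-6
python analysis/04_fit_spatial_models.py      # step 3: SAR fits, Δr², area check
python analysis/05_breakpoint_analysis.py     # split-line on elevational range
python analysis/06_robustness_completeness.py # subsample robustness + audits
```

each of which writes JSON/TSV reports under `results/`, or as a CLI
(`richdet generate|screen|select|sar|splitline|robustness|completeness|hotspots|run`).

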