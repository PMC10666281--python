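# Methods

`aqcausal` estimates the causal effect of a dated intervention (T0) on
monitored air-pollutant concentrations and attributes the spatial
heterogeneity of that effect to areal features. The chain is: meteorological
normalization → change-point response classification → donut sharp
regression discontinuity (RDD) in time → counterfactual exposure →
residual-kriging interpolation → gradient-boosted-tree + Shapley
attribution. Every stage is exercised end-to-end on a synthetic city with
known ground truth.

## 1. Meteorological normalization (de-weathering)

Hourly concentrations are modelled with a gradient-boosted tree regressor
(`HistGradientBoostingRegressor`) on eleven predictors: seven weather
variables (temperature, wind speed, wind direction, pressure, relative
humidity, rainfall, Monin–Obukhov length), three seasonal variables (hour
of day, day of week, day of year) and a time variable representing the
long-term trend. The model is fit on ln(concentration) by default
(`log_target`): atmospheric dilution is multiplicative, the downstream RDD
uses a log outcome, and the normalized series stays positive by
construction.

The normalized value at hour *t* averages model predictions over
`n_resamples` (default 200) complete covariate rows — weather and seasonal
variables drawn jointly, uniformly from the whole observed period — while
the time variable keeps its value at *t*. The observed-minus-fitted
residual is added back by default (`add_residual`) so abrupt deviations the
model under-fits, including the intervention step itself, survive into the
change-point stage. On the log scale this makes the normalized series
algebraically `obs − fitted + resampled-mean`: whatever the model assigns
to its *time profile* cancels between the second and third terms, and
whatever it assigns to weather/season is removed from the observations.

### Identifiability near an intervention

That cancellation cuts both ways, and it is the central numerical subtlety
of the method. On a short (2-year) record the time variable and day-of-year
are nearly collinear, and after T0 the post-period's seasonal composition
is *perfectly* confounded with the intervention step (every post-period day
has a unique day-of-year with no same-regime counterpart in another year).
Any trend or step the model misallocates to the resampled features is
incorrectly removed from the normalized series; any seasonality
misallocated to time is incorrectly retained. Deep, greedy trees get this
allocation wrong in ways that grow with the step size: diagnostics on the
synthetic world showed a ±1–3% systematic distortion at a −30% step, with
tree branches conditioned on the post-period extrapolating wildly when
evaluated at resampled winter days.

Three defaults keep the allocation honest:

* **Coarse time.** Time enters in 90-day blocks (`time_block_days`),
  anchored at T0 when the intervention date is known
  (`time_origin`, set automatically by the per-site driver). A coarse,
  boundary-aligned time feature can express the long-term trend and the
  step but cannot track sub-seasonal variation, and no block mixes pre-
  and post-intervention hours.
* **Shallow, gentle boosting.** Depth 3, learning rate 0.05, 400 trees
  (CV-tunable over a small grid). Deeper trees buy little held-out skill
  on this problem and pay for it in time×season interaction pathology;
  alternatives we evaluated and rejected — monotone time constraints,
  additive interaction constraints, a random-forest family — either failed
  to stop the misallocation or retained seasonality outright.
* **Quadratic RDD side-trends** (section 3), which absorb the smooth
  seasonal underfit that remains.

Model-fit uncertainty can be propagated with
`normalization_uncertainty`, which refits the model on multinomial
bootstrap weights over training hours and returns per-day percentile bands
of the normalized series; sites whose effect sign is unstable across
refits should be treated as non-robust.

Hourly normalized values are averaged to calendar days; a day is kept only
if at least `min_hours` (default 18) valid hours contribute.

## 2. Change-point detection and response classification

The normalized daily series is segmented by penalized piecewise-linear
least squares: each segment has its own intercept and slope, so both level
discontinuities and slope changes can occur at a breakpoint. The global
optimum is found by exact dynamic programming over an O(n²) segment-cost
matrix (prefix sums give each segment's linear-fit SSE in O(1)); the test
suite checks DP optimality against exhaustive enumeration of all
segmentations on short series. Each breakpoint pays `c·σ̂²·log n` with
`c = 3` (one `σ̂² log n` per breakpoint parameter: level, slope,
position); σ̂ is a MAD estimate from first differences, floored at 0.1% of
the data range so noise-free series keep a positive penalty. Minimum
segment length is 14 days. Breakpoints are labelled *level* when the fitted
jump exceeds `3σ̂/√min_seg_len`, else *slope*.

A site *responded* to the intervention if at least one change date falls
in the closed margin period `[T0 − hw, T0 + hw]`. The class default is
`hw = 7` days; the pipeline profile for the synthetic NO2-like pollutant
uses `hw = 14`, calibrated the way the original method prescribes — from
the observed timing spread of detected responses: at the smallest injected
effects (−5%), change-point localization scatter is about ±2 weeks.
The research window for the RDD runs between the nearest change points
*outside* the margin period (exclusive), clipped to the series extent;
change points inside the margin never clip.

## 3. Donut sharp RDD and the total effect

On the research window, ln(daily normalized concentration) is regressed on
a per-side polynomial in days-from-T0 (default order 2 — see below), the
treatment indicator D = 1[t ≥ T0], its trend interactions, and
`lag_order` autoregressive lags of the outcome (default chosen by AIC over
0..7). Days inside the margin period (the *donut hole*, equal to the
margin period) are excluded from the estimation rows, absorbing
anticipation and adaptation; lag regressors are built on the full window
so post-donut rows may reference donut-day observations. The coefficient
covariance is heteroskedasticity-robust (HC1).

With lags, the contemporaneous treatment coefficient β understates the
long-run change; the total effect propagates through the fitted dynamics:

    Δ = β / (1 − Σ ρ̂_j),   τ = exp(Δ) − 1,

which equals the steady-state step response of the fitted difference
equation (checked against forward simulation to 1e-8). Fits with
Σρ̂ ≥ 1 are rejected as non-stationary. τ is the relative change in daily
concentration attributable to the intervention.

Interval estimates draw `n_draws` (default 10,000) coefficient vectors
from N(β̂, Σ̂), map each through the total-effect transform (rejecting
non-stationary draws), and take percentile intervals at 90/95/99%;
significance at the 10/5/1% level is zero-exclusion of the matching
interval. With no lags this reproduces the closed-form quantiles of
exp(Normal)−1.

**Why order 2:** research windows can span many months per side. The
normalization leaves a smooth, years-shared seasonal underfit of order
±0.01–0.02 in log units; a purely linear side-trend integrates that
curvature into the discontinuity (≈ −0.01 bias in τ at τ = −0.3, with
interval coverage collapsing), while a quadratic side-trend absorbs it.
Local-linear (`order=1`) remains available.

## 4. Counterfactual exposure and aggregation

Site effects feed exposure as follows: τ̂ is the central estimate when the
site responded *and* the effect is significant at the 10% level, else 0.
The counterfactual (no-intervention) series divides observed post-T0
concentrations by (1 + τ̂); pre-period values are untouched. Observed
(raw, not normalized) concentrations enter the annual means — exposure is
a real-world quantity; normalization serves only estimation. Annual
impacts are φ = Ȳ_obs − Ȳ_counter (µg/m³) and φ% = φ / Ȳ_counter over the
dates both scenarios share (≥ 75% year coverage required). The scaling is
carried from T0 through year end with no decay model: any rebound within
the estimation window is already part of τ̂'s definition, and this is a
documented simplification.

City-level aggregates average τ̂ within site-type groups (roadside vs
background, optionally responders only) with a percentile bootstrap over
sites (default 10,000 resamples); groups under 3 sites are skipped.

## 5. Mapping by residual kriging

Site impacts {φ} and {φ%} are interpolated separately: ordinary least
squares on caller-supplied spatial covariates, then ordinary kriging of
the OLS residuals, summed on a regular grid of cell centers and averaged
(unweighted — cells are equal-area) to areal units. The semivariogram is
method-of-moments on distance bins, fit by weighted least squares (weights
= pair counts) with an exponential family by default; the kriging system
enforces unit-sum weights via a Lagrange multiplier and is exact at data
sites when the nugget is zero. Coordinates are planar kilometres
throughout — no geodesy. Networks with fewer than 10 sites fall back to
regression-only mapping with a warning.

## 6. Attribution with exact tree Shapley values

Gradient-boosted regression trees (scikit-learn, 3-fold CV over a small
grid of depth/learning rate/trees) map areal features to the impact
surface, separately for absolute (µg/m³) and relative (percentage-point)
targets when both are supplied; features with > 20% missing areas or zero
variance are dropped first. Contributions are Shapley values computed
*exactly*: within one tree the coalition value v(S) is the cover-weighted
conditional expectation by tree traversal (descend by the instance's value
when the split feature is in S, else average both children by training
cover), and the Shapley sum enumerates subsets of the features that tree
actually uses — valid because unused features are dummy players, and
cheap because boosted trees are shallow. Local accuracy (base value +
contributions = prediction) holds to machine precision and is asserted to
1e-6. Global importance is the mean |contribution| per feature with the
Pearson correlation between feature values and contributions; a
zero-variance contribution column reports correlation as undefined (NaN),
never 0. Total-gain importance (summed SSE reduction over splits) is
provided for comparison.

## 7. The synthetic city

The generator states a plausible mid-sized urban world; its defaults are
the package's stated test conditions and are not tuned to outcomes:

| parameter | default | rationale |
|---|---|---|
| record | 2019-01-01..2020-12-31 hourly | two full years around the intervention (scaled down from a 5-year study design for runtime) |
| T0 | 2020-03-23 | the intervention date of the motivating study |
| baseline | 35 µg/m³ (roadside +0.3 log) | urban NO2 levels |
| trend | −2% per year (log-linear) | long-term urban NO2 decline |
| noise | σ = 0.3 on hourly log scale | residual scatter after weather modelling |
| weather | diurnal+annual cycles, AR(1) ρ=0.9 | persistence of synoptic conditions |
| weather→conc | dilution 0.8/(1+wind), temperature U-shape, stability tanh(−L/50), washout | documented plausible physics, fully known to tests |
| site effects | configurable; −10% default, step at T0 | lockdown-scale responses; optional linear ramp to exercise the donut |
| areas | 200 centroids on a 40 km domain | MSOA-like density |
| areal impact | 3 linear features + 1 interaction + exponential GP (sill 0.3, range 8 km) + noise 0.15 | sparse causal structure under spatial confounding |

What a green test does **not** establish: the generator is additive in log
space with iid noise and a single shared weather station — real networks
have inter-site error correlation, instrument drift, chemistry
(NOx–O3 titration) and regional transport episodes, none of which are
emulated. Missingness is iid Bernoulli, not the burst pattern of real
outages.

## 8. Determinism and profiles

Every stochastic stage derives its seed from a master seed and the stage
name via SHA-256 (< 2³¹); identical configuration and master seed give
byte-identical CSV outputs. `PipelineConfig.fast_profile()` is the
documented scaled-down setting for repeated experiments (30 resamples,
200-tree normalizer without CV tuning, 4,000 MC draws, AIC lags 0..3); it
was verified to preserve bias/coverage behaviour before being adopted for
the validation experiments.

## Known limitations

* The margin period and CPD penalty are calibrated for the synthetic NO2
  world; other pollutants need their own margin analysis (the config is
  per-pollutant by design).
* The total-effect formula assumes the fitted AR dynamics are the true
  propagation mechanism; the forward-simulation oracle guarantees internal
  consistency, not external truth.
* Normalization-induced systematic error is mitigated, not eliminated;
  residual distortion of order ±0.005 in τ remains at large effects and is
  visible as slightly conservative interval behaviour in the validation
  tables.
* Kriging assumes second-order stationarity of regression residuals;
  strongly non-stationary residual fields would need trend re-estimation
  (out of scope).
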