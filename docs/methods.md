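# Methods

## Scope and model

`heatmort` implements the standard projection chain for heat-attributable
mortality under climate change: present-day exposure–response estimation,
multi-city pooling, classification of future summer days, and a health
impact function. The target setting is six large South Korean cities with
summertime (June 1 – September 30, 122 days) daily series of cause-specific
death counts, daily mean temperature, relative humidity, PM10 and ozone.

### Over-threshold risk model

For each city the association between high temperature and mortality is
modelled as log-linear *above* the city's summertime 75th-percentile daily
mean temperature `T_q`:

    log E(Y_t) = α + β T_{t−lag} + γ' DOW_t + ns(Time_t) + ns(RH_t)
                 + ns(PM10_t) + ns(O3_t)

fitted by quasi-Poisson (Poisson likelihood, standard errors scaled by the
square root of the Pearson dispersion φ̂) on the subset of days whose
lag-`l` temperature exceeds `T_q` (`l ∈ {0..3}`, single-day lags; the lag
never reaches across the September→June gap). The threshold restriction
operationalises the observation that exposure–response curves are
approximately linear above the 75th percentile; an exploratory penalized
spline curve (below) lets the user confirm this on their own data, but the
threshold is always the 75th percentile regardless of curve shape — cities
without a visually clear threshold are treated identically.

Confounder control: a 7-level day-of-week factor; one natural cubic spline
over the concatenated sequential day index with 2 df per summer (16 df for
8 summers), representing the long-term trend; 4-df natural cubic splines
for relative humidity and for each pollutant separately. Spline bases are
built with patsy's `cr` (interior knots at equally spaced quantiles of the
data entering the fit, boundary knots at the observed min/max). Because
`cr` spans the constant function, each term uses a (df+1)-column basis with
one column dropped, so that together with the model intercept the fitted
space matches R's `ns(x, df)` convention and the design stays full rank.
Rank deficiency and too-few-observations conditions raise typed errors
rather than silently pseudo-inverting. Days with missing values are
dropped listwise with a logged count.

Quantile convention: linear interpolation between order statistics
(numpy's default, R type 7), fixed for reproducibility. Percent change is
`(RR − 1) × 100` per 1 °C; confidence intervals are Wald on the log scale
and back-transformed, hence asymmetric.

### Exposure–response curve (exploratory)

A penalized cubic B-spline smooth of same-day temperature (10 basis
functions) with the same confounders entering unpenalized, fitted as a
Poisson GAM (statsmodels `GLMGam`). The penalty weight is chosen
automatically by AIC over a log-spaced grid spanning 10⁻² – 10⁷ — the data
determine the degree of smoothing. The curve is normalized to RR = 1 at
the series median temperature with a pointwise 95 % band. It is advisory
only; no fitting decision depends on it.

### Random-effects pooling

City log relative risks are pooled under `y_i ~ N(μ, se_i² + τ²)` with τ²
estimated by restricted maximum likelihood: Fisher scoring on τ² with the
estimate floored at zero, convergence at |Δτ²| < 1e-10, and a bounded
scalar minimisation of the negative restricted log-likelihood as fallback.
The pooled mean is the inverse-variance weighted average with weights
`1/(se_i² + τ²)`, `se = (Σw)^{-1/2}`, and a Wald 95 % CI — no
Knapp–Hartung small-sample adjustment, matching the convention of the
classical meta-analysis software this reproduces. Pooling is done on the
log-RR scale (pooling raw percent changes would be inconsistent with the
asymmetric CIs) and published percent-change tables are converted via
`se = [ln(1 + hi/100) − ln(1 + lo/100)] / (2 × 1.959964)`.

### Future day classification

With `T_q` the present and `T′_q` the future summertime 75th percentile:

* **shifted** days: future `T > T′_q`. Their increment `ΔT_shifted` is the
  difference of upper-quartile means (future minus present); the exposure
  is always `D = 30.5` days/year (25 % of 122; asserted constant — it is
  tied to the Jun–Sep window and would not survive a different window).
* **added** days: future `T_q < T ≤ T′_q`. Their increment `ΔT_added` is
  the mean exceedance over `T_q`; the exposure is the period-average count
  of such days per year (a 30-year period reports one per-year average,
  the only scale consistent with deaths *per year*).

Tie conventions (fixed and tested): days exactly at `T′_q` fall on the
added side; days exactly at `T_q` are excluded from the added set. If no
future day exceeds `T_q` at all there is no heat exposure beyond present
conditions and all increments and counts are zero; otherwise the formulas
are applied verbatim, and a cooler-than-present future yields a negative
`ΔT_shifted` which is reported, not clamped. Periods (e.g. 2041–2070,
2071–2100) are classified over all raw days of the period by default; a
day-of-year climatology mode (collapse each era to 122 day-of-year means
before classifying) is available behind a flag for users who prefer
climate-model-noise suppression, but raw-day statistics are the default
because they preserve the variance that drives the added-day count.

### Health impact function

    Δy = y₀ (e^{βΔT} − 1) × D          [deaths/year]

with `y₀` = baseline mortality rate × projected population (deaths/day).
The shifted and added components are computed separately and summed; the
sum is exact by construction for the mean and both CI bounds. CIs
substitute β's 95 % bounds into the formula — only risk-estimation
uncertainty is propagated; populations and temperature increments are
treated as fixed. Negative Δy (possible when a fitted β is negative) is
reported with a warning rather than clamped: transparency over cosmetics.
For β·ΔT < 0.02 the function is within 1 % of the linearization
`y₀βΔT·D` (tested).

Overall multi-city impacts use the pooled β with each city's own `y₀`,
`ΔT` and `D`, summed component-wise; per-city impacts use city-specific β.
Cause pairing follows the epidemiological finding that same-day exposure
fits all-cause mortality best while cardiovascular mortality peaks at a
1-day lag; respiratory mortality is excluded from projection (not
statistically significant in any city). An alternative accounting — sum
`y₀(e^{β·max(0, T_d − T_q)} − 1)` day by day in each era and difference the
annual means — is provided as a cross-validation of the shifted/added
decomposition; the two agree within a few percent on realistic scenarios.

Baseline rates: cause-specific 2008 rates are not published, so the
bundled profiles derive rates as mean summertime daily deaths ÷ 2008
population; externally supplied rates override this. The ≥65 analyses
accept age-specific populations but the bundled fixtures are all-ages.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
under which everything else is validated.

* **Temperature**: mean-zero half-sine seasonal cycle over the 122-day
  window (default amplitude 3 °C, peaking at mid-window ≈ August 1) plus
  AR(1) anomalies (default ρ = 0.6, a realistic day-to-day persistence),
  with the innovation variance set so the marginal SD matches the
  configured city SD. Summers are independent chains started at
  stationarity.
* **Confounders**: Gaussian with city-specific moments, clipped to
  physical ranges (RH to [0, 100] %, pollutants positive); the clip bias is
  well inside sampling error at the configured moments.
* **Deaths**: negative binomial with `Var = φ·mean` (φ ≥ 1, default 1.3 —
  mild overdispersion typical of daily death counts; quasi-Poisson has no
  generative form, and this parameterisation matches the fitting model's
  variance assumption exactly). The log-mean is baseline + β·max(0, T −
  T_q) + small linear confounder and day-of-week effects, where `T_q` is
  the realized 75th percentile of the generated temperatures. The planted
  β and realized `T_q` are recorded as ground truth. The five death
  columns (all-cause, CVD, respiratory, and their ≥65 versions at 70 % /
  75 % of the adult baselines) are drawn independently, sharing the city's
  planted β.
* **Defaults** are the six-city study conditions: published populations,
  death-count and weather moments, eight summers (2001–2008), and planted
  per-city log-RRs equal to the published all-cause percent changes
  (Seoul 2.62 %/°C etc.).
* **Future temperatures**: day-of-window seasonal mean (average over
  present years) plus whole present anomaly-years — bootstrap-resampled,
  or tiled in order ("copy" mode, which makes a constant offset an exact
  translation) — scaled by √(extra variance), plus the warming offset
  (optionally with a linear within-period trend). Default 30 future
  summers per period, mirroring 2041–2070 / 2071–2100. The realized
  upper-quartile shift is recorded as ground truth.

What the generator does **not** emulate: within-summer mortality
seasonality beyond an optional linear trend, cold effects, heat-wave
duration ("added wave") effects, mortality displacement, spatial
correlation between cities, missing data, and climate-model bias
structure. Passing tests therefore demonstrate correctness of the
estimation and projection machinery under the stated generative law, not
robustness to those real-data features.

## Numerical choices and degenerate inputs

* All randomness flows from integer seeds through numpy `SeedSequence`
  spawning (per-city child streams), so output is byte-identical under a
  fixed seed and adding cities does not perturb earlier draws.
* GLM fitting requires at least 5 more observations than parameters;
  otherwise a fitting error is raised. Rank deficiency raises rather than
  pseudo-inverting.
* REML: τ² floored at zero each scoring step; two consecutive floors
  terminate at the boundary (homogeneous data). Convergence 1e-10.
* Thresholds require ≥ 100 daily records. Identical temperatures give a
  degenerate but valid threshold.
* An empty added set is a logged zero, not an error; an empty shifted set
  (possible only under ties at the future quartile) reports a zero shift.
* Pipeline outputs are written with 10-significant-digit formatting; the
  in-memory invariants (e.g. exact additivity) hold to machine precision.

## Problem sizes

Default test and example runs use 8 summers × 122 days per city
(976 days), ~244 over-threshold days per fit, 30-summer future periods,
200 Monte-Carlo replicates for coverage experiments and 100 for null
coverage — sizes at which the coverage experiments are stable and the full
suite runs in well under a minute per module.

## Known limitations

* CI propagation ignores uncertainty in ΔT, D, populations and baseline
  rates; totals' CIs sum component bounds (perfect dependence through the
  shared β), consistent with the source convention but conservative.
* Single-model warming scenarios: no climate-ensemble spread, bias
  correction, or acclimatization scaling; no age/sex-resolved future
  populations; no socioeconomic vulnerability modelling.
* The over-threshold GLM conditions on a threshold estimated from the same
  series; the threshold's sampling variability is not propagated (standard
  practice, and immaterial at ~1000 days).
* The published per-city regression coefficients cannot be recomputed
  without the original meteorological/mortality microdata; reproduction
  targets are therefore the pooled estimates and the published-table
  arithmetic, plus full parameter recovery on synthetic data.
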