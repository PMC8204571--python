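# heatmort

Projection of climate-change-attributable heat mortality for city-level
daily time series, modelled on the six major South Korean cities (Seoul,
Incheon, Daejeon, Daegu, Gwangju, Busan) under RCP 4.5 and RCP 8.5 warming.

The package is for epidemiologists and health-impact modellers who need a
tested, reproducible implementation of the classic projection chain:

1. **City-specific risk** — summertime (Jun 1–Sep 30) daily death counts are
   regressed on daily mean temperature above the city's 75th-percentile
   threshold `T_q` with an over-threshold quasi-Poisson GLM,

   `log E(Y_t) = α + β T_{t−lag} + γ'DOW_t + ns(Time_t) + ns(RH_t) + ns(PM10_t) + ns(O3_t)`

   fitted only on days whose (lagged) temperature exceeds `T_q`, with
   natural cubic splines for the long-term trend (2 df per summer),
   relative humidity (4 df) and each pollutant (4 df), and standard errors
   inflated by √φ̂ (Pearson dispersion). Risks are reported as percent
   change per 1 °C, `(RR − 1) × 100`. A penalized-spline exposure–response
   curve (GAM) is available for exploratory threshold assessment.
2. **Pooling** — city log relative risks are combined with a
   random-effects meta-analysis, `y_i ~ N(μ, se_i² + τ²)`, with the
   heterogeneity variance τ² estimated by REML.
3. **Future day classification** — future summer days are split at the
   present (`T_q`) and future (`T′_q`) 75th percentiles into a **shifted**
   set (above `T′_q`: the upper quartile at a hotter level, always 30.5
   days/year = 25 % of the 122-day summer) and an **added** set
   (`T_q < T ≤ T′_q`: days newly exceeding the present threshold).
4. **Health impact** — each component's excess deaths per year follow
   `Δy = y₀ (e^{βΔT} − 1) D`, where `y₀` is expected baseline daily deaths
   (current mortality rate × projected population) and `D` the exposed
   days/year; totals are the exact sum of the two components, with CIs
   propagating only β's 95 % bounds.

A synthetic-data generator with planted effects (known β, known warming)
makes every stage testable end to end, and published six-city estimates are
bundled as reference inputs (`heatmort.reference`).

## Worked example

`python examples/05_project_impact.py` runs the whole chain for a
Seoul-like synthetic city (8 summers of present data, 30 future summers
with a 5.5 °C RCP 8.5-style offset) and prints:

```
shifted    382.7 deaths/year (95% CI   198.8,   578.5)  =  3.86 per 100k
added      553.3 deaths/year (95% CI   291.6,   824.3)  =  5.58 per 100k
total      936.1 deaths/year (95% CI   490.4,  1402.8)  =  9.43 per 100k

alternative day-by-day accounting: future 1073 - present 116 = 957 deaths/year
```

The shifted row is the upper summer quartile becoming ~5.3 °C hotter on its
fixed 30.5 days/year; the added row is ~82 days/year newly crossing the
present threshold by ~3 °C on average; their sum is the annual excess
mortality attributable to the warming, and the independent day-by-day
accounting of both eras lands within a few percent of it. Under strong
warming the added effect overtakes the shifted effect, exactly the
behaviour reported for end-of-century high-emission scenarios.

The other examples each demonstrate one capability: `01_simulate_data.py`
(generator + ground truth), `02_city_risk.py` (threshold, GAM curve,
over-threshold GLM), `03_pool_published.py` (REML pooling of the published
city rows), `04_classify_warming.py` (shifted/added day classification).

There is also a thin CLI (`heatmort simulate|fit-risk|pool|classify-climate|impact|run-all|validate`)
wrapping the same functions for shell use.

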