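"""Synthetic daily mortality/weather series with planted heat effects.

Emulates summertime (Jun 1 - Sep 30) daily series for Korean-style cities:
temperature follows a smooth seasonal half-sine plus AR(1) anomalies, the
confounders (relative humidity, PM10, ozone) are Gaussian with city-specific
moments, and death counts follow a negative-binomial law whose log-mean is

    log mu_t = baseline + beta * max(0, T_t - T_q) + confounder terms + DOW,

where ``T_q`` is the 75th percentile of the city's generated temperatures.
The negative binomial is parameterised so that Var = phi * mean, matching
the quasi-Poisson variance assumption of the fitting model (quasi-Poisson
itself has no generative form).  The generator records the planted ``beta``
and the realized ``T_q`` as ground truth, so every downstream stage can be
validated against known values.

Future temperature series are built by resampling present-day anomalies
around the seasonal mean and adding a warming offset; the realized shift in
the upper-quartile mean is recorded as ground-truth ``dT_shifted``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .errors import ConfigurationError, InputError
from .series import DailyCitySeries, summer_dates, write_series_csv

# mean-zero weekday effects on log mortality (Mon..Sun); weak, as observed
# for daily all-cause deaths
DEFAULT_DOW_COEFS = (0.01, 0.0, -0.005, 0.0, -0.005, -0.01, 0.01)


@dataclass
class ConfounderCoefs:
    """Log-scale effects of the (centred) confounders on daily mortality.

    Units: per %RH, per ug/m3 PM10, per ppb ozone.  Defaults are small
    positive effects of the size seen in summertime daily-mortality studies.
    """

    rh: float = 0.0005
    pm10: float = 0.0004
    o3: float = 0.0010
    dow: tuple[float, ...] = DEFAULT_DOW_COEFS


@dataclass
class CityParams:
    """Per-city generative parameters.

    ``baseline_log_rate`` is the log expected daily all-cause death count at
    reference conditions (confounders at their means, temperature at or
    below the threshold).  ``true_beta`` is the planted log relative risk
    per degC above the city's 75th-percentile temperature and applies to
    every cause column.
    """

    name: str
    baseline_log_rate: float
    true_beta: float
    temp_mean: float
    temp_sd: float
    rh_mean: float = 73.0
    rh_sd: float = 11.0
    pm10_mean: float = 45.0
    pm10_sd: float = 21.0
    o3_mean: float = 27.0
    o3_sd: float = 13.0
    #: log baseline rates of the other death columns; defaults derived from
    #: the all-cause baseline when None
    cvd_log_rate: float | None = None
    resp_log_rate: float | None = None
    elderly_fraction: float = 0.70      # >=65 share of all-cause deaths
    elderly_cvd_fraction: float = 0.75  # >=65 share of CVD deaths
    confounder_coefs: ConfounderCoefs = field(default_factory=ConfounderCoefs)
    overdispersion: float = 1.3
    seasonal_amplitude: float = 3.0  # degC, half-sine peak over the window
    ar1_rho: float = 0.6
    trend_per_summer: float = 0.0  # optional log-rate drift per summer

    def __post_init__(self) -> None:
        if not math.isfinite(self.true_beta):
            raise ConfigurationError(f"{self.name}: true_beta must be finite")
        if self.overdispersion < 1:
            raise ConfigurationError(f"{self.name}: overdispersion must be >= 1")
        for attr in ("temp_sd", "rh_sd", "pm10_sd", "o3_sd"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{self.name}: {attr} must be > 0")
        if not 0 <= self.ar1_rho < 1:
            raise ConfigurationError(f"{self.name}: ar1_rho must be in [0, 1)")

    def log_rates(self) -> dict[str, float]:
        """Baseline log rates for every death column."""
        cvd = self.cvd_log_rate
        if cvd is None:
            cvd = self.baseline_log_rate + math.log(0.27)
        resp = self.resp_log_rate
        if resp is None:
            resp = self.baseline_log_rate + math.log(0.05)
        return {
            "deaths_all": self.baseline_log_rate,
            "deaths_cvd": cvd,
            "deaths_resp": resp,
            "deaths_all_65p": self.baseline_log_rate + math.log(self.elderly_fraction),
            "deaths_cvd_65p": cvd + math.log(self.elderly_cvd_fraction),
        }


@dataclass
class SimulationConfig:
    """Configuration of a multi-city present-day simulation."""

    cities: list[CityParams]
    years: list[int] = field(default_factory=lambda: list(range(2001, 2009)))
    summer_window: tuple[tuple[int, int], tuple[int, int]] = ((6, 1), (9, 30))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cities:
            raise ConfigurationError("at least one city required")
        if not self.years:
            raise ConfigurationError("at least one summer year required")
        (m0, d0), (m1, d1) = self.summer_window
        n_days = (
            pd.Timestamp(2001, m1, d1) - pd.Timestamp(2001, m0, d0)
        ).days + 1
        if n_days != 122:
            raise ConfigurationError(
                f"summer window must span 122 days, got {n_days}"
            )

    @classmethod
    def reference_six_cities(
        cls, seed: int = 0, years: list[int] | None = None, **overrides
    ) -> "SimulationConfig":
        """Default study conditions: six cities with published moments.

        Baseline daily death rates, temperature and confounder moments come
        from the published summary table; the planted per-city log relative
        risks are the published all-cause, all-ages percent changes.
        """
        cities = []
        for name in reference.CITIES:
            st = reference.CITY_STATS[name]
            pct = reference.RISK_ESTIMATES[("all_cause", "all")][name][0]
            cities.append(
                CityParams(
                    name=name,
                    baseline_log_rate=math.log(st["deaths_all"][0]),
                    true_beta=math.log1p(pct / 100.0),
                    temp_mean=st["temp"][0],
                    temp_sd=st["temp"][1],
                    rh_mean=st["rh"][0],
                    rh_sd=st["rh"][1],
                    pm10_mean=st["pm10"][0],
                    pm10_sd=st["pm10"][1],
                    o3_mean=st["o3"][0],
                    o3_sd=st["o3"][1],
                    cvd_log_rate=math.log(st["deaths_cvd"][0]),
                    resp_log_rate=math.log(st["deaths_resp"][0]),
                    **overrides,
                )
            )
        return cls(cities=cities, years=years or list(range(2001, 2009)), seed=seed)


@dataclass
class CityTruth:
    """Ground truth recorded by the generator for one city."""

    true_beta: float
    t_q_true: float


@dataclass
class SimulationResult:
    """Generated present-day series plus the generator's ground truth."""

    series: list[DailyCitySeries]
    truth: dict[str, CityTruth]
    config: SimulationConfig

    def __iter__(self):
        return iter(self.series)

    def write(self, directory: str | Path) -> dict[str, Path]:
        """Write the series CSV and the ground-truth sidecar JSON."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        series_path = directory / "present_series.csv"
        truth_path = directory / "ground_truth.json"
        write_series_csv(self.series, series_path)
        truth_path.write_text(
            json.dumps({c: asdict(t) for c, t in self.truth.items()}, indent=2)
        )
        return {"series": series_path, "truth": truth_path}


def _seasonal_component(amplitude: float) -> np.ndarray:
    """Mean-zero half-sine over the 122-day window, peaking at mid-window
    (around Aug 1, i.e. early August)."""
    d = np.arange(122)
    s = amplitude * np.sin(np.pi * d / 121.0)
    return s - s.mean()


def _simulate_temperature(
    params: CityParams, n_years: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_years, 122) daily mean temperatures: seasonal + AR(1) anomalies."""
    seasonal = _seasonal_component(params.seasonal_amplitude)
    var_season = float(np.var(seasonal))
    var_anom = params.temp_sd**2 - var_season
    if var_anom <= 0:
        raise ConfigurationError(
            f"{params.name}: temp_sd too small for seasonal amplitude "
            f"{params.seasonal_amplitude}"
        )
    rho = params.ar1_rho
    innov_sd = math.sqrt(var_anom * (1 - rho**2))
    anom = np.empty((n_years, 122))
    # independent AR(1) chains per summer, started at stationarity
    anom[:, 0] = rng.normal(0.0, math.sqrt(var_anom), size=n_years)
    innov = rng.normal(0.0, innov_sd, size=(n_years, 121))
    for t in range(1, 122):
        anom[:, t] = rho * anom[:, t - 1] + innov[:, t - 1]
    return params.temp_mean + seasonal[None, :] + anom


def _draw_counts(
    mu: np.ndarray, phi: float, rng: np.random.Generator
) -> np.ndarray:
    """Counts with mean mu and variance phi*mu (Poisson when phi == 1)."""
    if phi == 1.0:
        return rng.poisson(mu)
    r = mu / (phi - 1.0)
    return rng.negative_binomial(r, r / (r + mu))


def generate_present_series(config: SimulationConfig) -> SimulationResult:
    """Generate present-day daily series for every configured city.

    Deterministic under a fixed ``config.seed``: per-city random streams are
    spawned from one seed sequence, so adding cities does not perturb the
    draws of earlier ones.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(config.cities))
    n_years = len(config.years)
    (m0, d0), _ = config.summer_window

    all_series: list[DailyCitySeries] = []
    truth: dict[str, CityTruth] = {}
    for params, child in zip(config.cities, children):
        rng = np.random.default_rng(child)
        temp = _simulate_temperature(params, n_years, rng)
        t_q = float(np.quantile(temp, 0.75))  # type-7 / linear interpolation
        excess = np.maximum(0.0, temp - t_q)

        rh = np.clip(
            rng.normal(params.rh_mean, params.rh_sd, temp.shape), 0.0, 100.0
        )
        pm10 = np.clip(
            rng.normal(params.pm10_mean, params.pm10_sd, temp.shape), 1.0, None
        )
        o3 = np.clip(
            rng.normal(params.o3_mean, params.o3_sd, temp.shape), 1.0, None
        )

        dates = pd.DatetimeIndex(
            np.concatenate([summer_dates(y).values for y in config.years])
        )
        dow = dates.dayofweek.to_numpy().reshape(temp.shape)
        cc = params.confounder_coefs
        year_idx = np.arange(n_years, dtype=float)[:, None]
        eta_common = (
            params.true_beta * excess
            + cc.rh * (rh - params.rh_mean)
            + cc.pm10 * (pm10 - params.pm10_mean)
            + cc.o3 * (o3 - params.o3_mean)
            + np.asarray(cc.dow)[dow]
            + params.trend_per_summer * (year_idx - (n_years - 1) / 2.0)
        )
        cols = {}
        for col, log_rate in params.log_rates().items():
            mu = np.exp(log_rate + eta_common)
            cols[col] = _draw_counts(mu, params.overdispersion, rng).ravel()

        df = pd.DataFrame(
            {
                "date": dates,
                **cols,
                "tmean_c": temp.ravel(),
                "rh_pct": rh.ravel(),
                "pm10_ugm3": pm10.ravel(),
                "o3_ppb": o3.ravel(),
            }
        )
        all_series.append(DailyCitySeries(city=params.name, data=df))
        truth[params.name] = CityTruth(true_beta=params.true_beta, t_q_true=t_q)
    return SimulationResult(series=all_series, truth=truth, config=config)


@dataclass
class FutureScenarioConfig:
    """Warming scenario applied when generating future temperatures.

    ``warming_offset_mean`` is the mean uniform warming (degC) over the
    period; ``warming_offset_trend`` adds a linear within-period trend
    (degC per year, centred so the period mean stays at the offset mean).
    ``mode`` is "bootstrap" (anomaly years resampled with replacement) or
    "copy" (present anomaly years tiled in order -- exact translation when
    the trend is zero and the variance scale is one).
    """

    scenario_label: str = "RCP8.5"
    period_label: str = "2071-2100"
    warming_offset_mean: float = 0.0
    warming_offset_trend: float = 0.0
    extra_variance_scale: float = 1.0
    start_year: int = 2071
    n_years: int = 30
    mode: str = "bootstrap"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.warming_offset_mean < 0:
            raise ConfigurationError("warming_offset_mean must be >= 0")
        if self.extra_variance_scale <= 0:
            raise ConfigurationError("extra_variance_scale must be > 0")
        if self.mode not in ("bootstrap", "copy"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_years < 1:
            raise ConfigurationError("n_years must be >= 1")


@dataclass
class FutureTemperatureSeries:
    """Future daily temperatures for one city plus realized ground truth."""

    city: str
    scenario: str
    period: str
    data: pd.DataFrame = field(repr=False)  # date, tmean_c
    dt_shifted_true: float = float("nan")

    @property
    def temps(self) -> np.ndarray:
        return self.data["tmean_c"].to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.insert(0, "city", self.city)
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def generate_future_temperatures(
    present: DailyCitySeries, scenario: FutureScenarioConfig
) -> FutureTemperatureSeries:
    """Build a future summertime temperature series from a present one.

    Present temperatures are decomposed into a day-of-window seasonal mean
    (average across present years) and anomalies.  Future years reuse whole
    present anomaly-years (resampled or tiled) scaled by
    ``sqrt(extra_variance_scale)``, plus the seasonal mean and the warming
    offset.  The realized difference between the upper-25% means of the
    future and present series is recorded as ``dt_shifted_true``.
    """
    if len(present) == 0:
        raise InputError("present series is empty")
    years = present.years
    temp = present.data.assign(year=present.data["date"].dt.year)
    mat = np.full((len(years), 122), np.nan)
    for i, y in enumerate(years):
        vals = temp.loc[temp["year"] == y, "tmean_c"].to_numpy()
        if len(vals) != 122:
            raise InputError(
                f"{present.city}: year {y} has {len(vals)} days, expected 122"
            )
        mat[i] = vals
    seasonal = mat.mean(axis=0)
    anom = mat - seasonal[None, :]

    rng = np.random.default_rng(np.random.SeedSequence(scenario.seed))
    if scenario.mode == "bootstrap":
        pick = rng.integers(0, len(years), size=scenario.n_years)
    else:
        pick = np.arange(scenario.n_years) % len(years)
    scale = math.sqrt(scenario.extra_variance_scale)
    yr_idx = np.arange(scenario.n_years, dtype=float)
    offsets = scenario.warming_offset_mean + scenario.warming_offset_trend * (
        yr_idx - (scenario.n_years - 1) / 2.0
    )
    fut = seasonal[None, :] + anom[pick] * scale + offsets[:, None]

    fut_years = range(scenario.start_year, scenario.start_year + scenario.n_years)
    dates = pd.DatetimeIndex(
        np.concatenate([summer_dates(y).values for y in fut_years])
    )
    data = pd.DataFrame({"date": dates, "tmean_c": fut.ravel()})

    pres_t = present.temps
    fut_t = fut.ravel()
    p75_p = np.quantile(pres_t, 0.75)
    p75_f = np.quantile(fut_t, 0.75)
    dt_true = float(fut_t[fut_t > p75_f].mean() - pres_t[pres_t > p75_p].mean())
    return FutureTemperatureSeries(
        city=present.city,
        scenario=scenario.scenario_label,
        period=scenario.period_label,
        data=data,
        dt_shifted_true=dt_true,
    )
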