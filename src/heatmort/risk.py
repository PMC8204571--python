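"""City-specific high-temperature mortality risk estimation.

The exposure of interest is daily mean temperature above the city's
summertime 75th percentile.  The working model is an over-threshold
quasi-Poisson GLM:

    log E(Y_t) = alpha + beta * T_{t-lag} + gamma' DOW_t
                 + ns(Time_t) + ns(RH_t) + ns(PM10_t) + ns(O3_t)

fitted only on days whose lagged temperature exceeds the threshold, with
natural cubic splines for the long-term trend (2 df per summer), relative
humidity (4 df) and each pollutant (4 df), and standard errors inflated by
the square root of the Pearson dispersion.  ``beta`` is the log relative
risk per degC; results are reported as percent change (RR - 1) x 100.

A penalized-spline exposure-response curve (GAM) over the full temperature
range is provided for exploratory threshold assessment; the threshold used
for fitting is always the 75th percentile regardless of curve shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from statsmodels.gam.api import BSplines, GLMGam

from .errors import FittingError, InputError, RankDeficiencyError
from .series import DailyCitySeries

Z975 = 1.959964

#: (cause, age_group) -> death-count column
CAUSE_COLUMNS = {
    ("all_cause", "all"): "deaths_all",
    ("all_cause", "ge65"): "deaths_all_65p",
    ("cardiovascular", "all"): "deaths_cvd",
    ("cardiovascular", "ge65"): "deaths_cvd_65p",
    ("respiratory", "all"): "deaths_resp",
}


@dataclass
class ModelSpec:
    """Specification of the over-threshold GLM for one cause/age/lag."""

    cause: str = "all_cause"
    age_group: str = "all"
    lag: int = 0
    df_time_per_summer: int = 2
    df_rh: int = 4
    df_pollutant: int = 4

    def __post_init__(self) -> None:
        if self.lag not in (0, 1, 2, 3):
            raise InputError(f"lag must be in 0..3, got {self.lag}")
        if (self.cause, self.age_group) not in CAUSE_COLUMNS:
            raise InputError(
                f"unknown cause/age combination ({self.cause}, {self.age_group})"
            )
        for attr in ("df_time_per_summer", "df_rh", "df_pollutant"):
            if getattr(self, attr) < 1:
                raise InputError(f"{attr} must be a positive integer")

    @property
    def death_column(self) -> str:
        return CAUSE_COLUMNS[(self.cause, self.age_group)]


@dataclass
class RiskEstimate:
    """Fitted over-threshold risk for one city and model specification."""

    city: str
    spec: ModelSpec
    threshold_Tq: float
    beta: float
    se_beta: float
    n_days_fitted: int
    dispersion: float
    alpha_intercept: float
    dow_coefs: dict[str, float] = field(default_factory=dict)

    @property
    def rr_per_degC(self) -> float:
        return math.exp(self.beta)

    @property
    def pct_change(self) -> float:
        return percent_change(self.rr_per_degC)

    @property
    def ci95(self) -> tuple[float, float]:
        """95% Wald CI of the percent change (log-scale, back-transformed)."""
        lo = math.exp(self.beta - Z975 * self.se_beta)
        hi = math.exp(self.beta + Z975 * self.se_beta)
        return (percent_change(lo), percent_change(hi))

    @property
    def beta_ci95(self) -> tuple[float, float]:
        return (self.beta - Z975 * self.se_beta, self.beta + Z975 * self.se_beta)

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "city": self.city,
            "cause": self.spec.cause,
            "age_group": self.spec.age_group,
            "lag": self.spec.lag,
            "threshold_Tq": self.threshold_Tq,
            "beta": self.beta,
            "se_beta": self.se_beta,
            "rr_per_degC": self.rr_per_degC,
            "pct_change": self.pct_change,
            "ci_low": lo,
            "ci_high": hi,
            "n_days_fitted": self.n_days_fitted,
            "dispersion": self.dispersion,
        }


@dataclass
class ExposureResponseCurve:
    """Penalized-spline exposure-response curve, RR = 1 at the median."""

    city: str
    temperature: np.ndarray
    rr: np.ndarray
    rr_low: np.ndarray
    rr_high: np.ndarray
    alpha_penalty: float

    def __post_init__(self) -> None:
        assert (self.rr > 0).all()


def percent_change(rr: float) -> float:
    """Percent change in mortality per 1 degC: (RR - 1) x 100."""
    if rr <= 0:
        raise InputError(f"relative risk must be positive, got {rr}")
    return (rr - 1.0) * 100.0


def compute_threshold(series: DailyCitySeries, quantile: float = 0.75) -> float:
    """Empirical temperature quantile over all summertime days.

    Uses linear interpolation between order statistics (numpy default,
    R type 7).  At the default quantile this is the 75th percentile
    threshold above which the over-threshold GLM is fitted.
    """
    if len(series) < 100:
        raise InputError(
            f"{series.city}: need >= 100 daily records, got {len(series)}"
        )
    if not 0 < quantile < 1:
        raise InputError("quantile must be in (0, 1)")
    return float(np.quantile(series.temps, quantile))


def _prepare(series: DailyCitySeries, spec: ModelSpec) -> tuple[pd.DataFrame, int]:
    """Lagged, confounder-complete modelling frame plus the time-spline df."""
    df = series.data.copy()
    df["dow"] = df["date"].dt.dayofweek
    df["year"] = df["date"].dt.year
    df["time_idx"] = np.arange(len(df), dtype=float)
    # lag within each summer only: a lag never reaches across the Sep->Jun gap
    df["temp_lag"] = df.groupby("year")["tmean_c"].shift(spec.lag)
    n_summers = df["year"].nunique()
    needed = ["temp_lag", "rh_pct", "pm10_ugm3", "o3_ppb", spec.death_column]
    n_before = len(df)
    df = df.dropna(subset=needed)
    n_dropped = n_before - len(df)
    expected_lag_losses = spec.lag * n_summers
    if n_dropped > expected_lag_losses:
        # listwise deletion of days with missing confounders
        import logging

        logging.getLogger(__name__).info(
            "%s: dropped %d days with missing values (%d from lagging)",
            series.city,
            n_dropped,
            expected_lag_losses,
        )
    return df, spec.df_time_per_summer * n_summers


def _ns_basis(x: np.ndarray, df: int, name: str) -> pd.DataFrame:
    """Natural cubic spline basis with ``df`` non-constant columns.

    Interior knots at equally spaced quantiles, boundary knots at the
    observed min/max (patsy ``cr`` defaults).  ``cr`` includes the constant
    in its span, so a (df+1)-column basis is built and one column dropped;
    together with the model intercept this spans the same space as R's
    ``ns(x, df)``.
    """
    basis = np.asarray(
        patsy.dmatrix(f"cr(x, df={df + 1}) - 1", {"x": np.asarray(x, float)})
    )[:, 1:]
    return pd.DataFrame(basis, columns=[f"ns({name})[{i}]" for i in range(df)])


def _confounder_matrix(df: pd.DataFrame, spec: ModelSpec, df_time: int) -> pd.DataFrame:
    """Intercept + DOW dummies + ns(time) + ns(RH) + ns(PM10) + ns(O3)."""
    n = len(df)
    blocks = [pd.DataFrame({"Intercept": np.ones(n)})]
    dow = pd.get_dummies(
        pd.Categorical(df["dow"], categories=range(7)), prefix="C(dow)", dtype=float
    ).iloc[:, 1:]  # Monday is the reference level
    blocks.append(dow.reset_index(drop=True))
    blocks.append(_ns_basis(df["time_idx"], df_time, "time_idx"))
    blocks.append(_ns_basis(df["rh_pct"], spec.df_rh, "rh_pct"))
    blocks.append(_ns_basis(df["pm10_ugm3"], spec.df_pollutant, "pm10_ugm3"))
    blocks.append(_ns_basis(df["o3_ppb"], spec.df_pollutant, "o3_ppb"))
    return pd.concat(blocks, axis=1)


def _design_matrix(df: pd.DataFrame, spec: ModelSpec, df_time: int) -> pd.DataFrame:
    X = _confounder_matrix(df, spec, df_time)
    X.insert(1, "temp_lag", df["temp_lag"].to_numpy(dtype=float))
    return X


def fit_quasipoisson(
    y: np.ndarray, X: np.ndarray | pd.DataFrame
) -> sm.regression.linear_model.RegressionResultsWrapper:
    """Quasi-Poisson GLM: Poisson log-link fit with SEs scaled by sqrt(phi).

    ``phi`` is the Pearson chi-square dispersion; ``result.scale`` holds it.
    Raises :class:`RankDeficiencyError` if the design is rank deficient.
    """
    Xa = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xa) < Xa.shape[1]:
        raise RankDeficiencyError(
            f"design matrix rank {np.linalg.matrix_rank(Xa)} < {Xa.shape[1]} columns"
        )
    model = sm.GLM(np.asarray(y, dtype=float), X, family=sm.families.Poisson())
    try:
        return model.fit(scale="X2")
    except Exception as exc:  # pragma: no cover - statsmodels failure paths
        raise FittingError(f"quasi-Poisson fit failed: {exc}") from exc


def fit_over_threshold_glm(
    series: DailyCitySeries, spec: ModelSpec, threshold: float
) -> RiskEstimate:
    """Fit the over-threshold quasi-Poisson GLM for one city.

    The fitting subset is the days whose lag-``l`` temperature (the exposure
    entering the model) exceeds ``threshold``; roughly the upper 25% of
    summertime days when the threshold is the 75th percentile.
    """
    df, df_time = _prepare(series, spec)
    sub = df[df["temp_lag"] > threshold]
    X = _design_matrix(sub, spec, df_time)
    n_params = X.shape[1]
    if len(sub) < n_params + 5:
        raise FittingError(
            f"{series.city}: only {len(sub)} over-threshold days for "
            f"{n_params} parameters"
        )
    res = fit_quasipoisson(sub[spec.death_column].to_numpy(), X)
    dow_coefs = {
        name: float(res.params[name]) for name in X.columns if name.startswith("C(dow)")
    }
    return RiskEstimate(
        city=series.city,
        spec=spec,
        threshold_Tq=float(threshold),
        beta=float(res.params["temp_lag"]),
        se_beta=float(res.bse["temp_lag"]),
        n_days_fitted=int(len(sub)),
        dispersion=float(res.scale),
        alpha_intercept=float(res.params["Intercept"]),
        dow_coefs=dow_coefs,
    )


def fit_exposure_response_gam(
    series: DailyCitySeries,
    spec: ModelSpec | None = None,
    df_smooth: int = 10,
    n_grid: int = 50,
    alphas: np.ndarray | None = None,
) -> ExposureResponseCurve:
    """Penalized-spline curve of log mortality against same-day temperature.

    The temperature smooth is a penalized cubic B-spline whose penalty
    weight is chosen automatically by AIC over a log-spaced grid (the data
    determine the degree of smoothing); the same confounders as the GLM
    enter unpenalized.  The returned curve is normalized to RR = 1 at the
    series median temperature, with a pointwise 95% band.
    """
    spec = spec or ModelSpec()
    df, df_time = _prepare(series, spec)
    y = df[spec.death_column].to_numpy(dtype=float)
    X = _confounder_matrix(df, spec, df_time)
    temps = df["tmean_c"].to_numpy(dtype=float)
    bs = BSplines(temps[:, None], df=[df_smooth], degree=[3])

    if alphas is None:
        alphas = 10.0 ** np.arange(-2, 8)
    best = None
    for a in alphas:
        try:
            r = GLMGam(
                y, exog=X, smoother=bs, family=sm.families.Poisson(), alpha=[float(a)]
            ).fit()
        except Exception as exc:
            raise FittingError(f"{series.city}: GAM fit failed at alpha={a}: {exc}")
        if best is None or r.aic < best[1]:
            best = (float(a), float(r.aic), r)
    alpha, _, res = best

    grid = np.linspace(temps.min(), temps.max(), n_grid)
    b_grid = bs.transform(grid[:, None])
    b_med = bs.transform(np.array([[np.median(temps)]]))
    diff = b_grid - b_med  # contrast vs median -> RR = 1 there
    k_par = X.shape[1]
    p_smooth = np.asarray(res.params)[k_par:]
    cov_smooth = np.asarray(res.cov_params())[k_par:, k_par:]
    log_rr = diff @ p_smooth
    se = np.sqrt(np.einsum("ij,jk,ik->i", diff, cov_smooth, diff))
    return ExposureResponseCurve(
        city=series.city,
        temperature=grid,
        rr=np.exp(log_rr),
        rr_low=np.exp(log_rr - Z975 * se),
        rr_high=np.exp(log_rr + Z975 * se),
        alpha_penalty=alpha,
    )


def estimates_to_frame(estimates: list[RiskEstimate]) -> pd.DataFrame:
    """Flat table of risk estimates (city, age_group, cause, lag, pct, CI)."""
    return pd.DataFrame([e.to_dict() for e in estimates])
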