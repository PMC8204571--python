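"""Risk-estimation tests: thresholds, GLM vs IRLS oracle, invariances, GAM."""

import numpy as np
import pandas as pd
import pytest

from heatmort.errors import FittingError, InputError, RankDeficiencyError
from heatmort.risk import (
    ModelSpec,
    compute_threshold,
    fit_exposure_response_gam,
    fit_over_threshold_glm,
    fit_quasipoisson,
    percent_change,
)
from heatmort.series import DailyCitySeries
from heatmort.simulate import generate_present_series

from conftest import series_from_temps, single_city_config


# --- threshold ---------------------------------------------------------------

def brute_force_quantile(values, q):
    """Order-statistic quantile with linear interpolation (independent of
    numpy): h = (n-1)q, result = x_(floor(h)) + frac(h) (x_(floor(h)+1) - x_(floor(h)))."""
    xs = sorted(values)
    h = (len(xs) - 1) * q
    lo = int(np.floor(h))
    if lo == len(xs) - 1:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def test_threshold_matches_order_statistic_enumeration():
    temps = np.arange(1.0, 101.0)  # 1..100, one each
    rng = np.random.default_rng(0)
    series = series_from_temps(rng.permutation(temps))
    assert compute_threshold(series) == pytest.approx(
        brute_force_quantile(temps, 0.75), abs=1e-12
    )
    assert compute_threshold(series) == pytest.approx(75.25, abs=1e-12)


def test_threshold_degenerate_and_input_checks():
    assert compute_threshold(series_from_temps(np.full(122, 20.0))) == 20.0
    with pytest.raises(InputError):
        compute_threshold(series_from_temps(np.arange(99.0)))
    with pytest.raises(InputError):
        compute_threshold(series_from_temps(np.arange(122.0)), quantile=1.5)


# --- percent change ----------------------------------------------------------

@pytest.mark.parametrize(
    "rr,expected", [(1.027, 2.7), (1.0, 0.0), (1.107, 10.7), (0.98, -2.0)]
)
def test_percent_change_values(rr, expected):
    assert percent_change(rr) == pytest.approx(expected, abs=1e-9)


def test_percent_change_rejects_nonpositive_rr():
    with pytest.raises(InputError):
        percent_change(0.0)


# --- quasi-Poisson GLM vs independent IRLS oracle ----------------------------

def irls_poisson(y, X, tol=1e-12, max_iter=200):
    """Textbook iteratively reweighted least squares for the Poisson GLM."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(max(y.mean(), 0.1))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(eta)
        z = eta + (y - mu) / mu
        W = mu
        WX = X * W[:, None]
        new = np.linalg.solve(X.T @ WX, WX.T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    raise RuntimeError("IRLS did not converge")


def test_glm_matches_irls_oracle_to_1e8():
    """Small no-spline instance: intercept + temperature + binary covariate."""
    rng = np.random.default_rng(123)
    n = 40
    temp = rng.uniform(25, 32, n)
    binary = (rng.random(n) < 0.5).astype(float)
    X = np.column_stack([np.ones(n), temp, binary])
    y = rng.poisson(np.exp(1.0 + 0.03 * temp - 0.1 * binary))
    res = fit_quasipoisson(y, X)
    oracle = irls_poisson(y, X)
    np.testing.assert_allclose(np.asarray(res.params), oracle, atol=1e-8)


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(1)
    X = np.column_stack([np.ones(30), rng.normal(size=30)])
    X = np.column_stack([X, X[:, 1]])  # duplicated column
    y = rng.poisson(3.0, 30)
    with pytest.raises(RankDeficiencyError):
        fit_quasipoisson(y, X)


# --- over-threshold GLM on synthetic data ------------------------------------

def test_glm_recovers_planted_effect(seoul_sim, seoul_series):
    truth = seoul_sim.truth["Seoul"]
    thr = compute_threshold(seoul_series)
    est = fit_over_threshold_glm(seoul_series, ModelSpec(), thr)
    lo, hi = est.beta_ci95
    assert lo < truth.true_beta < hi
    # ~25% of the 976 summertime days enter the fit
    assert 0.22 * len(seoul_series) < est.n_days_fitted <= 0.25 * len(seoul_series) + 1
    assert est.rr_per_degC == pytest.approx(np.exp(est.beta))
    assert est.pct_change == pytest.approx((est.rr_per_degC - 1) * 100)
    assert est.ci95[0] < est.pct_change < est.ci95[1]


def test_translation_equivariance(seoul_series):
    """Adding c to all temperatures shifts the threshold by c and leaves
    the slope (and its SE) unchanged."""
    thr = compute_threshold(seoul_series)
    est = fit_over_threshold_glm(seoul_series, ModelSpec(), thr)
    shifted = DailyCitySeries(
        city="Seoul", data=seoul_series.data.assign(tmean_c=seoul_series.data["tmean_c"] + 4.0)
    )
    thr2 = compute_threshold(shifted)
    assert thr2 == pytest.approx(thr + 4.0, abs=1e-10)
    est2 = fit_over_threshold_glm(shifted, ModelSpec(), thr2)
    assert est2.beta == pytest.approx(est.beta, abs=1e-6)
    assert est2.se_beta == pytest.approx(est.se_beta, rel=1e-5)


def test_scaling_deaths_shifts_intercept_not_slope(seoul_series):
    """Tripling every death count adds ln 3 to the intercept and leaves the
    temperature slope unchanged (score equations scale exactly)."""
    thr = compute_threshold(seoul_series)
    est = fit_over_threshold_glm(seoul_series, ModelSpec(), thr)
    scaled = DailyCitySeries(
        city="Seoul",
        data=seoul_series.data.assign(deaths_all=seoul_series.data["deaths_all"] * 3),
    )
    est3 = fit_over_threshold_glm(scaled, ModelSpec(), thr)
    assert est3.beta == pytest.approx(est.beta, abs=1e-6)
    assert est3.alpha_intercept - est.alpha_intercept == pytest.approx(np.log(3), abs=1e-5)


def test_dispersion_near_one_for_pure_poisson():
    cfg = single_city_config(seed=21, overdispersion=1.0)
    sim = generate_present_series(cfg)
    s = sim.series[0]
    est = fit_over_threshold_glm(s, ModelSpec(), compute_threshold(s))
    # phi_hat ~ chi2_df/df with df ~ 208: 3 sigma is about +-0.3
    assert 0.7 < est.dispersion < 1.3


def test_lag_subsets_on_lagged_exposure(seoul_series):
    thr = compute_threshold(seoul_series)
    est0 = fit_over_threshold_glm(seoul_series, ModelSpec(lag=0), thr)
    est2 = fit_over_threshold_glm(seoul_series, ModelSpec(lag=2), thr)
    # the lagged exposure defines the subset, so counts stay near 25%
    assert abs(est2.n_days_fitted - est0.n_days_fitted) < 20
    assert est2.spec.lag == 2


def test_too_small_subset_raises():
    rng = np.random.default_rng(5)
    n = 122
    s = series_from_temps(
        rng.normal(24, 2.8, n),
        deaths_all=rng.poisson(10, n),
        rh_pct=rng.uniform(50, 90, n),
        pm10_ugm3=rng.uniform(20, 80, n),
        o3_ppb=rng.uniform(10, 50, n),
    )
    # a 90th-percentile threshold leaves ~12 days, far fewer than parameters
    with pytest.raises(FittingError):
        fit_over_threshold_glm(s, ModelSpec(), compute_threshold(s, quantile=0.9))


def test_model_spec_validation():
    with pytest.raises(InputError):
        ModelSpec(lag=4)
    with pytest.raises(InputError):
        ModelSpec(cause="unknown")


# --- exposure-response GAM ----------------------------------------------------

def test_gam_detects_planted_threshold_shape():
    """Strong planted over-threshold effect: the fitted curve is ~flat below
    the true threshold and rises above it."""
    cfg = single_city_config(seed=33)
    cfg.cities[0].true_beta = np.log(1.10)
    sim = generate_present_series(cfg)
    s = sim.series[0]
    tq = sim.truth[s.city].t_q_true
    curve = fit_exposure_response_gam(s)
    log_rr = np.log(curve.rr)
    above = curve.temperature > tq
    below = (curve.temperature < tq - 0.5) & (curve.temperature > tq - 4.0)
    slope_above = np.polyfit(curve.temperature[above], log_rr[above], 1)[0]
    slope_below = np.polyfit(curve.temperature[below], log_rr[below], 1)[0]
    assert slope_above > 0.03
    assert slope_above > 3 * abs(slope_below)
    assert np.all(curve.rr_low <= curve.rr) and np.all(curve.rr <= curve.rr_high)


def test_gam_null_curve_stays_within_noise_band():
    """true_beta = 0: the fitted curve is near-flat and stays within its
    uncertainty.  The grid maximum of |log RR|/SE behaves like the max of a
    few effective z-scores, so 3.5 is the relevant noise ceiling (not the
    pointwise 2): checked over a handful of replicates allowing one excess."""
    hits = 0
    n_rep = 8
    for rep in range(n_rep):
        cfg = single_city_config(seed=100 + rep)
        cfg.cities[0].true_beta = 0.0
        s = generate_present_series(cfg).series[0]
        curve = fit_exposure_response_gam(s)
        log_rr = np.log(curve.rr)
        se = (np.log(curve.rr_high) - np.log(curve.rr_low)) / (2 * 1.959964)
        interior = se > 1e-12
        assert np.max(np.abs(log_rr)) < 0.3  # near-flat on the RR scale
        if np.max(np.abs(log_rr[interior]) / se[interior]) < 3.5:
            hits += 1
    assert hits >= n_rep - 1


def test_duplicated_data_same_curve_narrower_band(seoul_series):
    alphas = np.array([1000.0])  # fixed penalty so precision is comparable
    curve1 = fit_exposure_response_gam(seoul_series, alphas=alphas)
    twice = seoul_series.data.copy()
    shifted = twice.assign(date=twice["date"] + pd.DateOffset(years=8))
    doubled = DailyCitySeries(
        city="Seoul", data=pd.concat([twice, shifted], ignore_index=True)
    )
    curve2 = fit_exposure_response_gam(doubled, alphas=alphas)
    width1 = np.mean(np.log(curve1.rr_high) - np.log(curve1.rr_low))
    width2 = np.mean(np.log(curve2.rr_high) - np.log(curve2.rr_low))
    assert width2 < width1
    assert np.max(np.abs(np.log(curve2.rr) - np.log(curve1.rr))) < 0.1
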