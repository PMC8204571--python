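"""Day-classification tests: brute-force agreement, ties, translations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatmort.climate import (
    SHIFTED_DAYS_PER_YEAR,
    classify_future_days,
    summarize_periods,
)
from heatmort.errors import InputError
from heatmort.simulate import FutureScenarioConfig, generate_future_temperatures


def order_stat_quantile(values, q):
    """Independent linear-interpolation quantile (sorted order statistics)."""
    xs = sorted(float(v) for v in values)
    h = (len(xs) - 1) * q
    lo = int(h)
    if lo == len(xs) - 1:
        return xs[lo]
    return xs[lo] + (h - lo) * (xs[lo + 1] - xs[lo])


def brute_force_classify(present, future, n_years):
    """Day-by-day enumeration oracle for the shifted/added classification."""
    tq_p = order_stat_quantile(present, 0.75)
    tq_f = order_stat_quantile(future, 0.75)
    if not any(t > tq_p for t in future):
        return tq_p, tq_f, 0.0, 0.0, 0.0
    shifted, added = [], []
    for t in future:
        if t > tq_f:
            shifted.append(t)
        elif t > tq_p:  # tq_p < t <= tq_f
            added.append(t)
    pres_upper = [t for t in present if t > tq_p]
    dts = float(np.mean(shifted) - np.mean(pres_upper))
    dta = float(np.mean([t - tq_p for t in added])) if added else 0.0
    return tq_p, tq_f, dts, dta, len(added) / n_years


def test_identical_future_gives_zero_everything():
    rng = np.random.default_rng(0)
    temps = rng.normal(24, 3, 488)
    shift = classify_future_days(temps, temps.copy(), n_future_years=4)
    assert shift.dT_shifted == pytest.approx(0.0, abs=1e-12)
    assert shift.dT_added == 0.0
    assert shift.added_days_per_year == 0.0
    assert shift.Tq_future == pytest.approx(shift.Tq_present, abs=1e-12)


def test_uniform_translation_is_exact():
    """future = present + 2: dT_shifted = 2 exactly; the ADDED set equals the
    present days in (p75, p75 + 2], verified by exhaustive enumeration."""
    rng = np.random.default_rng(1)
    present = rng.normal(23.6, 2.8, 976)
    future = present + 2.0
    shift = classify_future_days(present, future, n_future_years=8)
    assert shift.dT_shifted == pytest.approx(2.0, abs=1e-9)
    p75 = order_stat_quantile(present, 0.75)
    expected_added = sum(1 for t in present if p75 < t + 2.0 <= p75 + 2.0)
    assert shift.added_days_per_year == pytest.approx(expected_added / 8)
    assert shift.Tq_future == pytest.approx(shift.Tq_present + 2.0, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    offset=st.floats(-1.0, 8.0),
    n_future_years=st.integers(1, 6),
)
def test_classification_matches_brute_force(seed, offset, n_future_years):
    rng = np.random.default_rng(seed)
    present = rng.normal(24, 3, 244)
    future = rng.normal(24 + offset, 3.2, 122 * n_future_years)
    shift = classify_future_days(present, future, n_future_years=n_future_years)
    tq_p, tq_f, dts, dta, apy = brute_force_classify(present, future, n_future_years)
    assert shift.Tq_present == pytest.approx(tq_p, abs=1e-9)
    assert shift.Tq_future == pytest.approx(tq_f, abs=1e-9)
    assert shift.dT_shifted == pytest.approx(dts, abs=1e-9)
    assert shift.dT_added == pytest.approx(dta, abs=1e-9)
    assert shift.added_days_per_year == pytest.approx(apy, abs=1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_partition_covers_every_future_day_once(seed):
    rng = np.random.default_rng(seed)
    present = rng.normal(24, 3, 366)
    future = rng.normal(27, 3, 366)
    shift = classify_future_days(present, future, n_future_years=3)
    n_shifted = int(np.sum(future > shift.Tq_future))
    n_added = int(np.sum((future > shift.Tq_present) & (future <= shift.Tq_future)))
    n_below = int(np.sum(future <= shift.Tq_present))
    assert n_shifted + n_added + n_below == len(future)


def test_tie_convention_at_thresholds():
    """Days exactly at T'_q side with ADDED; days exactly at T_q are not ADDED."""
    # present: quartile boundary exactly at 24.0; future: boundary at 28.0
    present = np.array([20.0] * 8 + [24.0] * 4)  # p75 = 24.0
    future = np.array([24.0] * 8 + [28.0] * 4)  # p75 = 28.0
    assert order_stat_quantile(present, 0.75) == 24.0
    shift = classify_future_days(present, future, n_future_years=1)
    # the eight days at exactly Tq_present = 24 are excluded (need strictly >)
    # and the four at exactly Tq_future = 28 are below-or-equal, hence ADDED
    assert shift.added_days_per_year == 4
    assert shift.dT_added == pytest.approx(4.0)
    assert shift.dT_shifted == 0.0  # shifted set empty -> no days > Tq_future


def test_shifted_days_constant_is_quarter_of_summer():
    assert SHIFTED_DAYS_PER_YEAR == 30.5 == 122 / 4
    rng = np.random.default_rng(3)
    shift = classify_future_days(
        rng.normal(24, 3, 244), rng.normal(27, 3, 244), n_future_years=2
    )
    assert shift.shifted_days_per_year == 30.5


def test_warming_monotonicity():
    """Uniform warming c >= 0 weakly increases dT_shifted, added days and
    total added heat (dT_added x added days)."""
    rng = np.random.default_rng(4)
    present = rng.normal(23.6, 2.8, 976)
    anomalies = rng.normal(0, 2.8, 122 * 30)
    prev = None
    for c in [0.0, 0.5, 1.5, 3.0, 5.5]:
        future = 23.6 + anomalies + c
        s = classify_future_days(present, future, n_future_years=30)
        total_added_heat = s.dT_added * s.added_days_per_year
        if prev is not None:
            assert s.dT_shifted >= prev[0] - 1e-9
            assert s.added_days_per_year >= prev[1] - 1e-9
            assert total_added_heat >= prev[2] - 1e-9
        prev = (s.dT_shifted, s.added_days_per_year, total_added_heat)


def test_future_colder_than_present_threshold_is_null():
    present = np.arange(20.0, 32.0, 0.1)
    future = np.full(120, 15.0)
    shift = classify_future_days(present, future, n_future_years=1)
    assert shift.dT_shifted == 0.0
    assert shift.dT_added == 0.0
    assert shift.added_days_per_year == 0.0


# --- period summaries ---------------------------------------------------------

def test_single_period_equals_direct_classification(seoul_series):
    scen = FutureScenarioConfig(
        warming_offset_mean=3.0, n_years=30, start_year=2071, seed=9
    )
    fut = generate_future_temperatures(seoul_series, scen)
    direct = classify_future_days(seoul_series, fut)
    [period] = summarize_periods(seoul_series, fut, [(2071, 2100)])
    assert period.dT_shifted == pytest.approx(direct.dT_shifted, abs=1e-12)
    assert period.dT_added == pytest.approx(direct.dT_added, abs=1e-12)
    assert period.added_days_per_year == pytest.approx(
        direct.added_days_per_year, abs=1e-12
    )


def test_periods_with_monotone_offsets_give_monotone_shift(seoul_series):
    """A positive within-period warming trend makes the later period hotter,
    so its shifted increment exceeds the earlier period's."""
    scen = FutureScenarioConfig(
        warming_offset_mean=3.0, warming_offset_trend=0.05,
        n_years=60, start_year=2041, seed=10,
    )
    fut = generate_future_temperatures(seoul_series, scen)
    early, late = summarize_periods(
        seoul_series, fut, [(2041, 2070), (2071, 2100)]
    )
    assert late.dT_shifted > early.dT_shifted


def test_empty_period_raises(seoul_series):
    scen = FutureScenarioConfig(n_years=10, start_year=2041, seed=1)
    fut = generate_future_temperatures(seoul_series, scen)
    with pytest.raises(InputError):
        summarize_periods(seoul_series, fut, [(2090, 2095)])


def test_climatology_mode_runs_and_smooths(seoul_series):
    scen = FutureScenarioConfig(
        warming_offset_mean=4.0, n_years=30, start_year=2071, seed=11
    )
    fut = generate_future_temperatures(seoul_series, scen)
    [raw] = summarize_periods(seoul_series, fut, [(2071, 2100)])
    [clim] = summarize_periods(
        seoul_series, fut, [(2071, 2100)], climatology_by_doy=True
    )
    # averaging by day of year removes most anomaly variance but keeps the
    # warming signal
    assert clim.dT_shifted == pytest.approx(4.0, abs=1.0)
    assert raw.dT_shifted == pytest.approx(4.0, abs=1.0)


# --- published increment scale ------------------------------------------------

@pytest.mark.parametrize(
    "city,scenario,period",
    [("Seoul", "RCP8.5", "2071-2100"), ("Incheon", "RCP8.5", "2071-2100")],
)
def test_published_increment_rows_are_consistent_with_translation(city, scenario, period):
    """Warming a city's present distribution by the published shifted
    increment yields added-day counts on the scale of the published rows.
    Only the offset (not the full future distribution) is controlled, so the
    tolerance is generous (+-12 days/year)."""
    from heatmort import reference

    dts, _, added_days = reference.TEMPERATURE_INCREMENTS[(city, scenario, period)]
    st_city = reference.CITY_STATS[city]
    rng = np.random.default_rng(abs(hash(city)) % 2**31)
    present = rng.normal(st_city["temp"][0], st_city["temp"][1], 122 * 10)
    future = np.tile(present, 3) + dts
    shift = classify_future_days(present, future, n_future_years=30)
    assert shift.dT_shifted == pytest.approx(dts, abs=1e-9)
    assert shift.added_days_per_year == pytest.approx(added_days, abs=12)
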