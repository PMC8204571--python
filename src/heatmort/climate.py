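"""Classification of future summer days into shifted and added heat exposure.

Let T_q be the 75th percentile of present summertime daily mean temperature
and T'_q that of the future summer.  Future days with T > T'_q are the
SHIFTED set: the upper quartile of the future summer, which replaces the
present upper quartile at a higher temperature level.  Future days with
T_q < T <= T'_q are the ADDED set: days newly exceeding the present
threshold that are not part of the future upper quartile.

The shifted temperature increment dT_shifted is the difference between the
upper-25% means of the future and present summers; the added increment
dT_added is the mean exceedance over T_q among ADDED days.  The shifted
effect always acts on 30.5 days per year (25% of the 122-day Jun-Sep
window); the added effect acts on |ADDED| / n_years days per year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError

#: 25% of the 122-day Jun-Sep summer window, days per year
SHIFTED_DAYS_PER_YEAR = 30.5


def _temps_and_years(obj, n_years: int | None) -> tuple[np.ndarray, int, np.ndarray | None]:
    """Extract (temperatures, n_years, calendar years per day) from input.

    Accepts a plain array (requires ``n_years``), a DataFrame with
    date/tmean_c columns, or anything with ``.temps`` and ``.data`` (e.g.
    DailyCitySeries / FutureTemperatureSeries).
    """
    years = None
    if hasattr(obj, "temps"):
        temps = np.asarray(obj.temps, dtype=float)
        dates = pd.to_datetime(obj.data["date"])
        years = dates.dt.year.to_numpy()
    elif isinstance(obj, pd.DataFrame):
        temps = obj["tmean_c"].to_numpy(dtype=float)
        years = pd.to_datetime(obj["date"]).dt.year.to_numpy()
    else:
        temps = np.asarray(obj, dtype=float)
    if years is not None:
        n = len(np.unique(years))
    elif n_years is not None:
        n = int(n_years)
    else:
        raise InputError("n_years required when passing a bare temperature array")
    if temps.size == 0:
        raise InputError("empty temperature series")
    return temps, n, years


@dataclass
class TemperatureShift:
    """Per city x scenario x period classification summary."""

    city: str
    scenario: str
    period: str
    Tq_present: float
    Tq_future: float
    dT_shifted: float
    dT_added: float
    added_days_per_year: float
    n_future_years: int
    shifted_days_per_year: float = SHIFTED_DAYS_PER_YEAR

    def to_dict(self) -> dict:
        return {
            "city": self.city,
            "scenario": self.scenario,
            "period": self.period,
            "Tq_present": self.Tq_present,
            "Tq_future": self.Tq_future,
            "dT_shifted": self.dT_shifted,
            "dT_added": self.dT_added,
            "added_days_per_year": self.added_days_per_year,
            "shifted_days_per_year": self.shifted_days_per_year,
            "n_future_years": self.n_future_years,
        }


def classify_future_days(
    present_temps,
    future_temps,
    n_future_years: int | None = None,
    city: str = "",
    scenario: str = "",
    period: str = "",
) -> TemperatureShift:
    """Classify future summer days against present/future 75th percentiles.

    Tie convention: days exactly at T'_q fall on the ADDED side (the
    shifted set requires strictly greater), and days exactly at T_q are
    excluded from ADDED (strictly greater than the present threshold is
    required).

    If no future day exceeds the present threshold at all, there is no heat
    exposure beyond present conditions and all increments and counts are
    reported as zero.
    """
    pres, _, _ = _temps_and_years(present_temps, n_years=1)
    fut, n_years, _ = _temps_and_years(future_temps, n_future_years)

    tq_p = float(np.quantile(pres, 0.75))
    tq_f = float(np.quantile(fut, 0.75))

    if not (fut > tq_p).any():
        return TemperatureShift(
            city=city, scenario=scenario, period=period,
            Tq_present=tq_p, Tq_future=tq_f,
            dT_shifted=0.0, dT_added=0.0, added_days_per_year=0.0,
            n_future_years=n_years,
        )

    shifted = fut[fut > tq_f]
    added = fut[(fut > tq_p) & (fut <= tq_f)]
    # shifted can be empty when the future maximum ties with its quartile
    dt_shifted = (
        float(shifted.mean() - pres[pres > tq_p].mean()) if shifted.size else 0.0
    )
    if added.size:
        dt_added = float((added - tq_p).mean())
        added_per_year = added.size / n_years
    else:
        dt_added = 0.0
        added_per_year = 0.0
    return TemperatureShift(
        city=city, scenario=scenario, period=period,
        Tq_present=tq_p, Tq_future=tq_f,
        dT_shifted=dt_shifted, dT_added=dt_added,
        added_days_per_year=added_per_year, n_future_years=n_years,
    )


def summarize_periods(
    present_temps,
    future_temps,
    period_bounds: list[tuple[int, int]],
    climatology_by_doy: bool = False,
    city: str = "",
    scenario: str = "",
) -> list[TemperatureShift]:
    """Classify each multi-year period of a future series separately.

    ``period_bounds`` is a list of inclusive (start_year, end_year) pairs.
    By default the classification statistics are computed over all raw days
    of the period; with ``climatology_by_doy`` both eras are first collapsed
    to day-of-year means (a 122-day climatology) before classifying.
    """
    fut, _, years = _temps_and_years(future_temps, None)
    if years is None:
        raise InputError("summarize_periods needs a dated future series")
    out = []
    for start, end in period_bounds:
        mask = (years >= start) & (years <= end)
        if not mask.any():
            raise InputError(f"period {start}-{end} has no days in the series")
        fut_p = fut[mask]
        n_years = len(np.unique(years[mask]))
        label = f"{start}-{end}"
        if climatology_by_doy:
            pres_arr, n_pres, pres_years = _temps_and_years(present_temps, 1)
            fut_clim = fut_p.reshape(n_years, -1).mean(axis=0)
            if pres_years is not None:
                n_p = len(np.unique(pres_years))
                pres_in = pres_arr.reshape(n_p, -1).mean(axis=0)
            else:
                pres_in = pres_arr
            shift = classify_future_days(
                pres_in, fut_clim, n_future_years=1,
                city=city, scenario=scenario, period=label,
            )
        else:
            shift = classify_future_days(
                present_temps, fut_p, n_future_years=n_years,
                city=city, scenario=scenario, period=label,
            )
        out.append(shift)
    return out


def shifts_to_frame(shifts: list[TemperatureShift]) -> pd.DataFrame:
    """Flat table (city, scenario, period, dT_shifted, dT_added, added days)."""
    return pd.DataFrame([s.to_dict() for s in shifts])
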