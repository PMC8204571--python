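"""Excess mortality attributable to climate change (health impact function).

The health impact function converts a log-linear risk coefficient beta
(log-RR per degC above threshold), a temperature increment dT, the expected
baseline daily deaths y0 and the number of exposed days per year D into
attributable deaths per year:

    dy = y0 * (exp(beta * dT) - 1) * D

The shifted component uses the upper-quartile temperature increment with
D = 30.5 days/year; the added component uses the mean exceedance of newly
added days with D = added days/year; the total is their sum.  Confidence
intervals propagate only the statistical uncertainty of beta, by
substituting its 95% CI bounds into the formula (populations and
temperature increments are treated as fixed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import TemperatureShift
from .errors import InputError
from .pooling import PooledRisk
from .risk import RiskEstimate

logger = logging.getLogger(__name__)


@dataclass
class CityProfile:
    """Population and baseline mortality inputs for one city.

    ``baseline_rates`` maps (cause, age_group) to deaths per person per day
    (base-year daily deaths divided by base-year population).
    """

    city: str
    pop_base: float
    pop_projection: float
    latitude: float = float("nan")
    baseline_rates: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pop_base <= 0 or self.pop_projection <= 0:
            raise InputError(f"{self.city}: populations must be positive")
        for key, rate in self.baseline_rates.items():
            if not 0 <= rate < 1:
                raise InputError(f"{self.city}: rate {key} out of (0, 1): {rate}")

    @classmethod
    def from_daily_deaths(
        cls,
        city: str,
        pop_base: float,
        pop_projection: float,
        daily_deaths: dict[tuple[str, str], float],
        latitude: float = float("nan"),
    ) -> "CityProfile":
        """Derive per-person daily rates from base-year mean daily deaths."""
        rates = {k: v / pop_base for k, v in daily_deaths.items()}
        return cls(
            city=city,
            pop_base=pop_base,
            pop_projection=pop_projection,
            latitude=latitude,
            baseline_rates=rates,
        )


def reference_profiles() -> dict[str, CityProfile]:
    """Profiles of the six reference cities from the published summary table.

    Baseline rates are derived from mean summertime daily deaths divided by
    the 2008 population (cause-specific 2008 rates are not published);
    externally supplied rates can be passed to :class:`CityProfile` instead.
    """
    from . import reference

    out = {}
    for name in reference.CITIES:
        st = reference.CITY_STATS[name]
        daily = {
            ("all_cause", "all"): st["deaths_all"][0],
            ("cardiovascular", "all"): st["deaths_cvd"][0],
            ("respiratory", "all"): st["deaths_resp"][0],
        }
        out[name] = CityProfile.from_daily_deaths(
            city=name,
            pop_base=st["pop_2008"],
            pop_projection=st["pop_2040"],
            daily_deaths=daily,
            latitude=reference.LATITUDE[name],
        )
    return out


def baseline_daily_deaths(
    profile: CityProfile, cause: str = "all_cause", age_group: str = "all"
) -> float:
    """Expected daily deaths without climate change: rate x projected pop."""
    key = (cause, age_group)
    if key not in profile.baseline_rates:
        raise InputError(f"{profile.city}: no baseline rate for {key}")
    return profile.baseline_rates[key] * profile.pop_projection


def health_impact(y0: float, beta: float, dT: float, D: float) -> float:
    """dy = y0 (e^{beta dT} - 1) D, excess deaths per year."""
    if y0 < 0:
        raise InputError(f"y0 must be >= 0, got {y0}")
    if D < 0:
        raise InputError(f"D must be >= 0, got {D}")
    dy = y0 * math.expm1(beta * dT) * D
    if dy < 0:
        logger.warning("negative excess mortality (%.2f): beta=%.4g dT=%.2f", dy, beta, dT)
    return dy


@dataclass
class ExcessMortality:
    """Annual excess deaths for one component (shifted, added or total)."""

    label: str  # city name or "overall"
    scenario: str
    period: str
    cause: str
    effect_component: str  # shifted | added | total
    deaths_per_year: float
    ci95: tuple[float, float]
    population: float
    inputs_echo: dict = field(default_factory=dict)

    @property
    def per_100k(self) -> float:
        """Deaths per 100,000 persons per year (projection population)."""
        return self.deaths_per_year / self.population * 100_000.0

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "scenario": self.scenario,
            "period": self.period,
            "cause": self.cause,
            "component": self.effect_component,
            "deaths_per_year": self.deaths_per_year,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "per_100k": self.per_100k,
        }


@dataclass
class ExcessTriple:
    """Shifted, added and total excess mortality for one city/scenario/period."""

    shifted: ExcessMortality
    added: ExcessMortality
    total: ExcessMortality

    def __iter__(self):
        return iter((self.shifted, self.added, self.total))


def sum_components(shifted: ExcessMortality, added: ExcessMortality) -> ExcessMortality:
    """Total = shifted + added, exactly, for the mean and both CI bounds."""
    return ExcessMortality(
        label=shifted.label,
        scenario=shifted.scenario,
        period=shifted.period,
        cause=shifted.cause,
        effect_component="total",
        deaths_per_year=shifted.deaths_per_year + added.deaths_per_year,
        ci95=(
            shifted.ci95[0] + added.ci95[0],
            shifted.ci95[1] + added.ci95[1],
        ),
        population=shifted.population,
        inputs_echo={"shifted": shifted.inputs_echo, "added": added.inputs_echo},
    )


def project_excess(
    risk: RiskEstimate | PooledRisk,
    shift: TemperatureShift,
    profile: CityProfile,
    cause: str = "all_cause",
    age_group: str = "all",
) -> ExcessTriple:
    """Project shifted/added/total annual excess deaths for one city.

    The shifted component applies (dT_shifted, D = 30.5 days/year); the
    added component applies (dT_added, D = added days/year); CI bounds
    substitute beta's 95% CI bounds into the impact function.
    """
    if isinstance(risk, RiskEstimate):
        if risk.city != shift.city:
            raise InputError(
                f"risk is for {risk.city!r} but shift is for {shift.city!r}"
            )
        beta, beta_ci = risk.beta, risk.beta_ci95
        label = shift.city
    else:
        beta, beta_ci = risk.pooled_beta, risk.beta_ci95
        label = shift.city or "overall"

    y0 = baseline_daily_deaths(profile, cause, age_group)

    def component(name: str, dT: float, D: float) -> ExcessMortality:
        return ExcessMortality(
            label=label,
            scenario=shift.scenario,
            period=shift.period,
            cause=cause,
            effect_component=name,
            deaths_per_year=health_impact(y0, beta, dT, D),
            ci95=(
                health_impact(y0, beta_ci[0], dT, D),
                health_impact(y0, beta_ci[1], dT, D),
            ),
            population=profile.pop_projection,
            inputs_echo={"y0": y0, "beta": beta, "dT": dT, "D": D},
        )

    shifted = component("shifted", shift.dT_shifted, shift.shifted_days_per_year)
    added = component("added", shift.dT_added, shift.added_days_per_year)
    return ExcessTriple(shifted=shifted, added=added, total=sum_components(shifted, added))


def project_excess_overall(
    pooled: PooledRisk,
    shifts: dict[str, TemperatureShift],
    profiles: dict[str, CityProfile],
    cause: str = "all_cause",
    age_group: str = "all",
) -> ExcessTriple:
    """Overall multi-city impact: pooled beta with city-specific y0, dT, D.

    Each city's components are computed with the pooled risk coefficient
    and summed across cities (component-wise, including CI bounds).
    """
    if set(shifts) - set(profiles):
        raise InputError(f"missing profiles for {sorted(set(shifts) - set(profiles))}")
    triples = [
        project_excess(pooled, shifts[c], profiles[c], cause, age_group)
        for c in sorted(shifts)
    ]
    first = triples[0]
    total_pop = sum(profiles[c].pop_projection for c in shifts)

    def summed(name: str) -> ExcessMortality:
        comps = [getattr(t, name) for t in triples]
        return ExcessMortality(
            label="overall",
            scenario=first.shifted.scenario,
            period=first.shifted.period,
            cause=cause,
            effect_component=name,
            deaths_per_year=sum(c.deaths_per_year for c in comps),
            ci95=(
                sum(c.ci95[0] for c in comps),
                sum(c.ci95[1] for c in comps),
            ),
            population=total_pop,
            inputs_echo={c.label: c.inputs_echo for c in comps},
        )

    shifted, added = summed("shifted"), summed("added")
    return ExcessTriple(shifted=shifted, added=added, total=sum_components(shifted, added))


def alternative_method_comparison(
    risk: RiskEstimate | PooledRisk,
    present_temps,
    future_temps,
    profile: CityProfile,
    threshold: float | None = None,
    n_present_years: int | None = None,
    n_future_years: int | None = None,
    cause: str = "all_cause",
    age_group: str = "all",
) -> tuple[float, float, float]:
    """Day-by-day heat-attributable deaths for both eras, and the difference.

    For each era, sums y0 (e^{beta max(0, T_d - T_q)} - 1) over days and
    divides by the number of years, where T_q is the present 75th-percentile
    threshold for both eras.  Returns (present_annual, future_annual,
    future - present); the difference is an alternative estimate of
    climate-attributable excess mortality against which the shifted/added
    decomposition can be cross-validated.
    """
    from .climate import _temps_and_years

    pres, n_p, _ = _temps_and_years(present_temps, n_present_years)
    fut, n_f, _ = _temps_and_years(future_temps, n_future_years)
    beta = risk.beta if isinstance(risk, RiskEstimate) else risk.pooled_beta
    if threshold is None:
        if isinstance(risk, RiskEstimate):
            threshold = risk.threshold_Tq
        else:
            threshold = float(np.quantile(pres, 0.75))
    y0 = baseline_daily_deaths(profile, cause, age_group)

    def annual(temps: np.ndarray, n_years: int) -> float:
        excess = np.maximum(0.0, temps - threshold)
        return float(y0 * np.expm1(beta * excess).sum() / n_years)

    present_annual = annual(pres, n_p)
    future_annual = annual(fut, n_f)
    return present_annual, future_annual, future_annual - present_annual


def excess_to_frame(results: list[ExcessMortality]) -> pd.DataFrame:
    """Flat table of excess-mortality results with per-100k columns."""
    return pd.DataFrame([r.to_dict() for r in results])
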