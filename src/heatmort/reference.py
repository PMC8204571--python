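"""Published six-city reference inputs for South Korea.

Bundles the published city-level summary statistics, temperature-mortality
risk estimates, projected summertime temperature increments under RCP 4.5
and RCP 8.5, and the corresponding excess-mortality projections for the six
major South Korean cities (Seoul, Incheon, Daejeon, Daegu, Gwangju, Busan;
summertime June-September, 2001-2008 baseline).

These numbers play two roles:

* as *inputs* -- e.g. the city-specific percent changes and confidence
  intervals are the raw material for random-effects pooling, and the summary
  moments parameterize the synthetic-data generator's default configuration;
* as *fixtures* -- published totals and ratios give exact arithmetic checks
  for the impact-projection stage.

Percent changes are per 1 degC increase in daily mean temperature above the
city's 75th-percentile summertime threshold.
"""

from __future__ import annotations

CITIES = ("Seoul", "Incheon", "Daejeon", "Daegu", "Gwangju", "Busan")

#: City latitude (degrees north); cities span ~35-38 N.
LATITUDE = {
    "Seoul": 37.57,
    "Incheon": 37.46,
    "Daejeon": 36.35,
    "Daegu": 35.87,
    "Gwangju": 35.16,
    "Busan": 35.10,
}

#: Summertime (Jun-Sep, 2001-2008) summary statistics per city:
#: populations for 2008 (base) and 2040 (projection year), mean (SD) daily
#: death counts by cause, daily mean temperature mean (SD) and 75th
#: percentile (degC), relative humidity (%), PM10 (ug/m3), ozone (ppb).
CITY_STATS = {
    "Seoul": {
        "pop_2008": 10_081_017, "pop_2040": 9_924_373,
        "deaths_all": (88.5, 10.0), "deaths_cvd": (23.7, 5.0), "deaths_resp": (4.7, 2.3),
        "temp": (23.6, 2.8), "temp_p75": 25.5,
        "rh": (70.7, 12.2), "pm10": (48.7, 28.2), "o3": (27.7, 13.9),
    },
    "Incheon": {
        "pop_2008": 2_681_825, "pop_2040": 3_036_476,
        "deaths_all": (25.2, 5.2), "deaths_cvd": (7.1, 2.8), "deaths_resp": (1.5, 1.2),
        "temp": (23.0, 2.6), "temp_p75": 24.9,
        "rh": (76.6, 11.2), "pm10": (48.5, 23.7), "o3": (29.5, 13.0),
    },
    "Daejeon": {
        "pop_2008": 1_497_857, "pop_2040": 1_566_886,
        "deaths_all": (12.9, 3.6), "deaths_cvd": (3.4, 1.8), "deaths_resp": (0.9, 1.0),
        "temp": (23.6, 2.9), "temp_p75": 25.6,
        "rh": (73.7, 10.4), "pm10": (35.3, 17.8), "o3": (12.9, 3.5),
    },
    "Daegu": {
        "pop_2008": 2_475_410, "pop_2040": 2_220_439,
        "deaths_all": (25.9, 5.2), "deaths_cvd": (6.8, 2.7), "deaths_resp": (1.5, 1.3),
        "temp": (24.4, 3.4), "temp_p75": 27.0,
        "rh": (69.6, 11.2), "pm10": (45.5, 18.5), "o3": (32.1, 14.7),
    },
    "Gwangju": {
        "pop_2008": 1_462_133, "pop_2040": 1_437_531,
        "deaths_all": (13.4, 3.6), "deaths_cvd": (3.1, 1.7), "deaths_resp": (0.8, 1.0),
        "temp": (24.1, 2.9), "temp_p75": 26.2,
        "rh": (74.3, 10.0), "pm10": (38.8, 20.8), "o3": (28.9, 12.8),
    },
    "Busan": {
        "pop_2008": 3_506_377, "pop_2040": 3_014_946,
        "deaths_all": (42.7, 6.8), "deaths_cvd": (12.7, 3.6), "deaths_resp": (2.3, 1.5),
        "temp": (23.8, 2.9), "temp_p75": 25.4,
        "rh": (77.3, 10.3), "pm10": (50.6, 19.9), "o3": (31.1, 12.0),
    },
}

#: Published percent change in mortality (with 95% CI) per 1 degC above the
#: city threshold, keyed by (cause, age_group).  Causes: all_cause,
#: cardiovascular (1-day lag), respiratory.  Age groups: all, ge65.
RISK_ESTIMATES = {
    ("all_cause", "all"): {
        "Seoul": (2.62, 1.20, 4.05),
        "Incheon": (2.80, -0.02, 5.70),
        "Daejeon": (0.14, -4.81, 5.35),
        "Daegu": (3.48, 0.37, 6.67),
        "Gwangju": (2.50, -1.96, 7.16),
        "Busan": (3.02, 0.54, 5.55),
    },
    ("all_cause", "ge65"): {
        "Seoul": (3.30, 1.47, 5.17),
        "Incheon": (2.96, -0.74, 6.80),
        "Daejeon": (1.36, -5.22, 8.39),
        "Daegu": (5.76, 1.62, 10.06),
        "Gwangju": (5.72, -0.23, 12.01),
        "Busan": (2.68, -0.31, 5.76),
    },
    ("cardiovascular", "all"): {
        "Seoul": (1.17, -1.41, 3.82),
        "Incheon": (8.57, 2.45, 15.06),
        "Daejeon": (10.66, 0.43, 21.92),
        "Daegu": (5.18, -0.88, 11.60),
        "Gwangju": (-2.08, -11.47, 8.31),
        "Busan": (3.10, -1.82, 8.26),
    },
    ("cardiovascular", "ge65"): {
        "Seoul": (0.08, -2.74, 2.99),
        "Incheon": (12.48, 4.55, 21.01),
        "Daejeon": (11.31, -1.28, 25.51),
        "Daegu": (4.33, -2.14, 11.23),
        "Gwangju": (-1.37, -12.63, 11.34),
        "Busan": (4.97, -0.63, 10.90),
    },
    ("respiratory", "all"): {
        "Seoul": (0.51, -5.28, 6.65),
        "Incheon": (5.70, -5.30, 17.97),
        "Daejeon": (3.41, -16.68, 28.33),
        "Daegu": (0.32, -12.11, 14.50),
        "Gwangju": (-5.87, -24.4, 17.20),
        "Busan": (6.68, -4.20, 18.80),
    },
    ("respiratory", "ge65"): {
        "Seoul": (2.55, -3.85, 9.38),
        "Incheon": (0.96, -10.77, 14.22),
        "Daejeon": (5.75, -15.72, 32.69),
        "Daegu": (-3.73, -16.55, 11.06),
        "Gwangju": (-2.25, -22.45, 23.20),
        "Busan": (7.52, -4.31, 20.82),
    },
}

#: Published pooled (six-city random-effects) percent changes.
POOLED_ESTIMATES = {
    ("all_cause", "all"): (2.70, 1.67, 3.73),
    ("all_cause", "ge65"): (3.44, 2.13, 4.76),
    ("cardiovascular", "all"): (3.81, 0.82, 6.89),
    ("cardiovascular", "ge65"): (4.56, 0.40, 8.89),
    ("respiratory", "all"): (2.06, -2.19, 6.50),
    ("respiratory", "ge65"): (2.35, -2.28, 7.19),
}

#: Projected summertime temperature increments (degC) and added days per
#: year, keyed (city, scenario, period) -> (dT_shifted, dT_added, added_days).
TEMPERATURE_INCREMENTS = {
    ("Seoul", "RCP4.5", "2041-2070"): (2.0, 0.8, 35),
    ("Seoul", "RCP4.5", "2071-2100"): (2.6, 1.2, 54),
    ("Seoul", "RCP8.5", "2041-2070"): (3.2, 1.3, 62),
    ("Seoul", "RCP8.5", "2071-2100"): (5.5, 2.9, 88),
    ("Incheon", "RCP4.5", "2041-2070"): (2.3, 0.7, 34),
    ("Incheon", "RCP4.5", "2071-2100"): (3.1, 1.2, 49),
    ("Incheon", "RCP8.5", "2041-2070"): (3.5, 1.2, 56),
    ("Incheon", "RCP8.5", "2071-2100"): (5.9, 2.9, 80),
    ("Daejeon", "RCP4.5", "2041-2070"): (1.9, 0.7, 16),
    ("Daejeon", "RCP4.5", "2071-2100"): (2.5, 0.9, 38),
    ("Daejeon", "RCP8.5", "2041-2070"): (3.2, 1.3, 38),
    ("Daejeon", "RCP8.5", "2071-2100"): (5.4, 2.5, 73),
    ("Daegu", "RCP4.5", "2041-2070"): (2.5, 0.6, 11),
    ("Daegu", "RCP4.5", "2071-2100"): (2.9, 0.6, 30),
    ("Daegu", "RCP8.5", "2041-2070"): (3.7, 1.5, 33),
    ("Daegu", "RCP8.5", "2071-2100"): (5.6, 2.3, 75),
    ("Gwangju", "RCP4.5", "2041-2070"): (2.0, 1.1, 16),
    ("Gwangju", "RCP4.5", "2071-2100"): (2.6, 1.0, 38),
    ("Gwangju", "RCP8.5", "2041-2070"): (3.1, 1.2, 44),
    ("Gwangju", "RCP8.5", "2071-2100"): (5.2, 2.5, 75),
    ("Busan", "RCP4.5", "2041-2070"): (2.2, 1.3, 19),
    ("Busan", "RCP4.5", "2071-2100"): (2.8, 1.2, 47),
    ("Busan", "RCP8.5", "2041-2070"): (3.4, 1.6, 53),
    ("Busan", "RCP8.5", "2071-2100"): (5.3, 2.9, 76),
}

#: Published six-city excess mortality (deaths/year), keyed
#: (cause, scenario, period) -> {"shifted"|"added"|"total": (mean, lo, hi)}.
EXCESS_MORTALITY = {
    ("all_cause", "RCP4.5", "2041-2070"): {
        "shifted": (388.1, 243.6, 548.7),
        "added": (111.8, 69.5, 154.5),
        "total": (499.9, 313.1, 703.1),
    },
    ("all_cause", "RCP4.5", "2071-2100"): {
        "shifted": (504.7, 315.9, 715.9),
        "added": (261.0, 162.1, 360.0),
        "total": (765.7, 478.0, 1076.8),
    },
    ("all_cause", "RCP8.5", "2041-2070"): {
        "shifted": (619.2, 386.4, 880.9),
        "added": (389.1, 241.3, 539.0),
        "total": (1008.4, 627.6, 1420.0),
    },
    ("all_cause", "RCP8.5", "2071-2100"): {
        "shifted": (1046.7, 645.9, 1505.9),
        "added": (1272.9, 783.9, 1775.1),
        "total": (2319.5, 1429.8, 3280.9),
    },
    ("cardiovascular", "RCP4.5", "2041-2070"): {
        "shifted": (149.7, 31.8, 275.1),
        "added": (42.1, 9.1, 76.0),
        "total": (191.8, 40.9, 351.1),
    },
    ("cardiovascular", "RCP4.5", "2071-2100"): {
        "shifted": (195.3, 41.1, 362.5),
        "added": (98.4, 21.2, 177.9),
        "total": (293.7, 62.4, 540.4),
    },
    ("cardiovascular", "RCP8.5", "2041-2070"): {
        "shifted": (240.4, 50.2, 450.2),
        "added": (147.0, 31.6, 267.1),
        "total": (387.4, 81.7, 717.3),
    },
    ("cardiovascular", "RCP8.5", "2071-2100"): {
        "shifted": (411.4, 83.1, 796.7),
        "added": (484.3, 102.0, 897.7),
        "total": (895.7, 185.1, 1694.4),
    },
}

#: Seoul narrative values for RCP8.5 2071-2100: shifted 427, added 626,
#: total 1053 deaths/year; and the alternative day-by-day accounting giving
#: 1158 (future) - 77 (present) = 1081 deaths/year.
SEOUL_RCP85_2071_2100 = {"shifted": 427.0, "added": 626.0, "total": 1053.0}
SEOUL_ALTERNATIVE_METHOD = {"present": 77.0, "future": 1158.0, "difference": 1081.0}


def published_city_estimates(cause: str = "all_cause", age_group: str = "all"):
    """Return the six published city rows for a cause/age group.

    Returns
    -------
    list of (city, pct_change, ci_low, ci_high) tuples, in latitude order.
    """
    table = RISK_ESTIMATES[(cause, age_group)]
    return [(c, *table[c]) for c in CITIES]
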