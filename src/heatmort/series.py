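"""Daily city-level series container and CSV round-trip.

A :class:`DailyCitySeries` holds one city's summertime daily records:
cause- and age-specific death counts, daily mean temperature and the
confounders entering the regression model (relative humidity, PM10, ozone).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InputError

#: canonical column order of the daily-series CSV schema
SERIES_COLUMNS = [
    "city",
    "date",
    "deaths_all",
    "deaths_cvd",
    "deaths_resp",
    "deaths_all_65p",
    "deaths_cvd_65p",
    "tmean_c",
    "rh_pct",
    "pm10_ugm3",
    "o3_ppb",
]

DEATH_COLUMNS = [c for c in SERIES_COLUMNS if c.startswith("deaths")]

#: summertime window (month, day) inclusive
SUMMER_START = (6, 1)
SUMMER_END = (9, 30)


def summer_dates(year: int) -> pd.DatetimeIndex:
    """The 122 summertime dates (Jun 1 - Sep 30) of ``year``."""
    return pd.date_range(
        pd.Timestamp(year, *SUMMER_START), pd.Timestamp(year, *SUMMER_END)
    )


@dataclass
class DailyCitySeries:
    """One city's ordered summertime daily records.

    ``data`` has a ``date`` column (datetime64) plus the death, temperature
    and confounder columns of :data:`SERIES_COLUMNS`.
    """

    city: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if "date" not in df.columns:
            raise InputError(f"{self.city}: series must have a 'date' column")
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        df = df.sort_values("date").reset_index(drop=True)
        if df["date"].duplicated().any():
            dups = df.loc[df["date"].duplicated(), "date"].dt.date.tolist()
            raise InputError(f"{self.city}: duplicated dates {dups[:5]}")
        in_summer = df["date"].dt.month.between(6, 9)
        if not in_summer.all():
            raise InputError(
                f"{self.city}: {int((~in_summer).sum())} records outside Jun-Sep"
            )
        for col in DEATH_COLUMNS:
            if col in df.columns:
                vals = df[col].to_numpy()
                if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                    raise InputError(f"{self.city}: {col} must be non-negative integers")
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def temps(self) -> np.ndarray:
        """Daily mean temperatures (degC) in date order."""
        return self.data["tmean_c"].to_numpy(dtype=float)

    @property
    def years(self) -> list[int]:
        return sorted(self.data["date"].dt.year.unique().tolist())

    @property
    def n_summers(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """The series as a flat DataFrame with a leading ``city`` column."""
        df = self.data.copy()
        df.insert(0, "city", self.city)
        return df[[c for c in SERIES_COLUMNS if c in df.columns]]

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().assign(date=lambda d: d["date"].dt.strftime("%Y-%m-%d")).to_csv(
            path, index=False
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, city: str | None = None) -> "DailyCitySeries":
        if city is None:
            cities = df["city"].unique()
            if len(cities) != 1:
                raise InputError("frame holds multiple cities; pass city=")
            city = str(cities[0])
        sub = df[df.get("city", city) == city] if "city" in df.columns else df
        return cls(city=city, data=sub.drop(columns=["city"], errors="ignore"))


def read_series_csv(path: str | Path) -> list[DailyCitySeries]:
    """Read a daily-series CSV (possibly multi-city) into per-city series."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = set(SERIES_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing columns {sorted(missing)}")
    return [DailyCitySeries.from_frame(df, city=c) for c in df["city"].unique()]


def write_series_csv(series: Iterable[DailyCitySeries], path: str | Path) -> None:
    """Write one or more city series to a single CSV."""
    frames = [s.to_frame() for s in series]
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
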