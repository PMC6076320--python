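"""Soil-temperature day classification and snow-cover estimation.

A logger day is *suitable* for amoebal growth when its mean soil temperature
lies between -0.5 and 2 degC and the diurnal fluctuation (max - min) stays
below 3 degC - the signature of an insulating snowpack. A day is
*unsuitable* (soil frost, potentially lethal to myxamoebae) when the
temperature never rises above -0.5 degC. Days meeting neither rule are
"neither"; days with too few readings are "insufficient_data" and excluded
from both counts. The two classes are mutually exclusive by construction
(a suitable mean >= -0.5 forces max >= -0.5) and this is asserted on every run.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, DataError

SUITABLE = "suitable"
UNSUITABLE = "unsuitable"
NEITHER = "neither"
INSUFFICIENT = "insufficient_data"


@dataclass(frozen=True)
class ThermalPolicy:
    mean_low: float = -0.5
    mean_high: float = 2.0
    max_fluctuation: float = 3.0  # strict: a day at exactly 3.0 is "neither"
    frost_max: float = -0.5
    min_readings_per_day: int = 24

    def __post_init__(self) -> None:
        if not self.mean_low < self.mean_high:
            raise ContractError("ThermalPolicy requires mean_low < mean_high")
        if self.frost_max > self.mean_low:
            raise ContractError("ThermalPolicy requires frost_max <= mean_low")


@dataclass
class LoggerSeries:
    site: str
    elevation: float
    readings: pd.DataFrame  # columns: timestamp (datetime64), temp_C

    def __post_init__(self) -> None:
        ts = self.readings["timestamp"]
        if ts.duplicated().any():
            raise DataError(f"site {self.site}: duplicate timestamps")
        if not ts.is_monotonic_increasing:
            raise DataError(f"site {self.site}: timestamps not increasing")

    @classmethod
    def read_csv(cls, path: str | Path, site: str = "", elevation: float = float("nan")) -> "LoggerSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(site=site or Path(path).stem, elevation=elevation, readings=df)

    def write_csv(self, path: str | Path) -> None:
        out = self.readings.copy()
        out["temp_C"] = out["temp_C"].map(lambda v: f"{v:.2f}")
        out.to_csv(path, index=False)


def classify_day(mean: float, tmin: float, tmax: float, n: int,
                 policy: ThermalPolicy) -> str:
    """Apply the suitability rule to one day's aggregates."""
    if n < policy.min_readings_per_day:
        return INSUFFICIENT
    if tmax < policy.frost_max:
        return UNSUITABLE
    if policy.mean_low <= mean <= policy.mean_high and (tmax - tmin) < policy.max_fluctuation:
        return SUITABLE
    return NEITHER


def daily_aggregate(series: LoggerSeries, policy: ThermalPolicy | None = None) -> pd.DataFrame:
    """Per-calendar-day mean/min/max/fluctuation and suitability class.

    Grouping is by the logger's local calendar date over the raw readings.
    """
    policy = policy or ThermalPolicy()
    if series.readings.empty:
        raise ContractError("daily_aggregate: empty series")
    df = series.readings
    g = df.groupby(df["timestamp"].dt.normalize())["temp_C"]
    out = g.agg(mean="mean", min="min", max="max", n="count").reset_index(names="date")
    out["fluctuation"] = out["max"] - out["min"]
    out["class"] = [
        classify_day(r.mean, r.min, r.max, r.n, policy)
        for r in out.itertuples(index=False)
    ]
    both = (out["class"] == SUITABLE) & (out["max"] < policy.frost_max)
    assert not both.any(), "a day classified suitable also satisfies the frost rule"
    return out


def winter_label(date: pd.Timestamp, start_month: int = 10) -> str:
    """Label 'YY/YY' of the winter a date belongs to (Oct-Jun by default)."""
    y = date.year if date.month >= start_month else date.year - 1
    return f"{y % 100:02d}/{(y + 1) % 100:02d}"


@dataclass
class SeasonStats:
    site: str
    winter: str
    suitable_days: int
    unsuitable_days: int
    neither_days: int
    insufficient_days: int

    @property
    def total_days(self) -> int:
        return (self.suitable_days + self.unsuitable_days
                + self.neither_days + self.insufficient_days)


def season_stats(daily: pd.DataFrame, site: str = "",
                 window: tuple[int, int] = (10, 6)) -> list[SeasonStats]:
    """Per-winter suitable/unsuitable day counts (window Oct 1 - Jun 30).

    ``window`` gives the first and last month of the winter season; days in
    other months are ignored. Counts over the four classes always sum to the
    number of window days present.
    """
    if daily.empty:
        raise ContractError("season_stats: no daily summaries")
    start_month, end_month = window
    dates = pd.to_datetime(daily["date"])
    in_window = (dates.dt.month >= start_month) | (dates.dt.month <= end_month)
    sub = daily.loc[in_window].copy()
    sub["winter"] = [winter_label(d, start_month) for d in pd.to_datetime(sub["date"])]
    out = []
    for winter, grp in sub.groupby("winter", sort=True):
        cls = grp["class"].value_counts()
        out.append(SeasonStats(
            site=site,
            winter=winter,
            suitable_days=int(cls.get(SUITABLE, 0)),
            unsuitable_days=int(cls.get(UNSUITABLE, 0)),
            neither_days=int(cls.get(NEITHER, 0)),
            insufficient_days=int(cls.get(INSUFFICIENT, 0)),
        ))
        assert out[-1].total_days == len(grp)
    return out


def season_table(stats: Sequence[SeasonStats], elevations: dict[str, float] | None = None) -> pd.DataFrame:
    rows = [{
        "site": s.site,
        "elevation_m": (elevations or {}).get(s.site, float("nan")),
        "winter": s.winter,
        "suitable_days": s.suitable_days,
        "unsuitable_days": s.unsuitable_days,
        "neither_days": s.neither_days,
        "insufficient_days": s.insufficient_days,
    } for s in stats]
    return pd.DataFrame(rows)


@dataclass
class SnowCover:
    n_days: int
    longest_run: int
    baseline_cm: float


def snow_cover_days(snow: pd.DataFrame, threshold_cm: float = 10.0,
                    max_gap_days: int = 0) -> SnowCover | None:
    """Count snow-covered days from an ultrasonic height series.

    During the snow-free season the sensor records the reflection of the
    surrounding vegetation, so the baseline is estimated as the snow-free
    median: the July-September daily median when summer months are present,
    else the 10th percentile of all daily medians. A day is covered when its
    median height exceeds baseline + ``threshold_cm``; runs broken by gaps
    of at most ``max_gap_days`` uncovered days count as contiguous (bridged
    days are not added to the total).
    """
    if snow.empty or snow["height_cm"].dropna().empty:
        return None
    df = snow.dropna(subset=["height_cm"])
    daily = df.groupby(df["timestamp"].dt.normalize())["height_cm"].median()
    summer = daily[daily.index.month.isin([7, 8, 9])]
    baseline = float(summer.median()) if len(summer) else float(np.percentile(daily, 10))
    covered = daily > baseline + threshold_cm
    n_days = int(covered.sum())
    longest = run = gap = 0
    for day, c in covered.items():
        if c:
            run += 1
            gap = 0
            longest = max(longest, run)
        else:
            gap += 1
            if gap > max_gap_days:
                run = 0
    return SnowCover(n_days=n_days, longest_run=longest, baseline_cm=baseline)
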