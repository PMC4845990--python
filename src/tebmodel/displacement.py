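"""Gland-level ductal growth: nipple-to-front displacement over age.

Whole-gland measurements give the straight-line distance from the nipple to
the advancing ductal front at weekly ages, either directly or as a percent
of fat-pad length filled.  Per-interval displacement rates and an ordinary
least-squares trend summarise growth for comparison with the model's
displacement-rate prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import DataError

__all__ = [
    "GlandRecord",
    "GlandTimeCourse",
    "front_distance",
    "interval_rates",
    "linear_trend",
    "read_gland_course",
]

DAYS_PER_WEEK = 7.0


class GlandRecord(NamedTuple):
    age_weeks: float
    nipple_to_front_mm: float
    gland_id: str = "g1"
    fat_pad_length_mm: Optional[float] = None


@dataclass
class GlandTimeCourse:
    records: list[GlandRecord]

    def __post_init__(self) -> None:
        for r in self.records:
            if r.nipple_to_front_mm < 0:
                raise DataError("front distance must be >= 0")
            if r.fat_pad_length_mm is not None and r.nipple_to_front_mm > r.fat_pad_length_mm:
                raise DataError("front distance cannot exceed fat-pad length")

    def mean_by_age(self) -> pd.Series:
        """Replicate glands averaged per age (ages sorted ascending)."""
        df = pd.DataFrame(self.records)
        return df.groupby("age_weeks")["nipple_to_front_mm"].mean().sort_index()


def front_distance(percent_filled: float, fat_pad_length_mm: float) -> float:
    """Nipple-to-front distance from percent of fat pad filled."""
    if not 0 <= percent_filled <= 100:
        raise DataError("percent filled must lie in [0, 100]")
    return percent_filled / 100.0 * fat_pad_length_mm


class IntervalRates(NamedTuple):
    rates_mm_day: list[float]
    mean_rate_mm_day: float


def interval_rates(tc: GlandTimeCourse) -> IntervalRates:
    """Per consecutive-age displacement rates (mm/day) and their mean.

    Replicates at one age are averaged first.  The mean of the interval
    rates weights each interval by its length, so it equals
    (last - first) / total days.
    """
    series = tc.mean_by_age()
    if len(series) < 2:
        raise DataError("need at least 2 ages")
    ages = series.index.to_numpy(dtype=float)
    dist = series.to_numpy(dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise DataError("ages must be strictly increasing")
    rates = list(np.diff(dist) / (np.diff(ages) * DAYS_PER_WEEK))
    mean = float((dist[-1] - dist[0]) / ((ages[-1] - ages[0]) * DAYS_PER_WEEK))
    return IntervalRates([float(r) for r in rates], mean)


def linear_trend(tc: GlandTimeCourse) -> tuple[float, tuple[float, float]]:
    """OLS slope of distance vs age across all gland replicates, in mm/day.

    Returns (slope, 95% CI).  Fitted on raw per-gland points, not age means.
    """
    df = pd.DataFrame(tc.records)
    if len(df) < 3 or df["age_weeks"].nunique() < 2:
        raise DataError("need >= 3 points over >= 2 ages for a trend")
    x = sm.add_constant(df["age_weeks"].to_numpy(dtype=float) * DAYS_PER_WEEK)
    fit = sm.OLS(df["nipple_to_front_mm"].to_numpy(dtype=float), x).fit()
    ci = fit.conf_int()[1]
    return float(fit.params[1]), (float(ci[0]), float(ci[1]))


def read_gland_course(path: str | Path) -> GlandTimeCourse:
    """Read a gland table: age_weeks, gland_id, fat_pad_length_mm and either
    nipple_to_front_mm or percent_filled."""
    df = pd.read_csv(path)
    if "age_weeks" not in df.columns:
        raise DataError("gland file needs an age_weeks column")
    records = []
    for _, row in df.iterrows():
        fat = row.get("fat_pad_length_mm")
        fat = None if fat is None or pd.isna(fat) else float(fat)
        if "nipple_to_front_mm" in df.columns and not pd.isna(row.get("nipple_to_front_mm")):
            dist = float(row["nipple_to_front_mm"])
        elif "percent_filled" in df.columns and fat is not None:
            dist = front_distance(float(row["percent_filled"]), fat)
        else:
            raise DataError("each row needs nipple_to_front_mm or percent_filled + fat pad length")
        records.append(
            GlandRecord(float(row["age_weeks"]), dist, str(row.get("gland_id", "g1")), fat)
        )
    return GlandTimeCourse(records)
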