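"""Per-class coverage fractions and seasonal/interannual time series.

Coverage is the fraction of *valid* lake pixels (cloud- or mask-invalid
pixels are excluded from the denominator so that missing data does not
deflate coverage).  Dated coverage records are assembled into a long-format
(year, season, class, fraction) table for trend analysis.

Season mapping follows the study's image windows — April-May is spring and
July-August is summer — with the remaining months mapped to meteorological
seasons (Mar-May spring, Jun-Aug summer, Sep-Nov autumn, Dec-Feb winter),
which the two windows are subsets of.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import CLASS_NAMES, ClassMap

__all__ = ["CoverageRecord", "coverage_fraction", "build_timeseries", "season_of", "SEASONS"]

SEASONS = ("spring", "summer", "autumn", "winter")

_MONTH_SEASON = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}


def season_of(date: str | _dt.date | _dt.datetime | pd.Timestamp) -> str:
    """Season of a calendar date (see module docstring for the mapping)."""
    ts = pd.Timestamp(date)
    if pd.isna(ts):
        raise ValueError(f"unparseable date: {date!r}")
    return _MONTH_SEASON[ts.month]


@dataclass
class CoverageRecord:
    """Per-date class coverage over the lake."""

    date: pd.Timestamp
    season: str
    fractions: dict[str, float]
    valid_pixel_count: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")
        if self.valid_pixel_count <= 0:
            raise ValueError("valid_pixel_count must be positive")
        total = sum(self.fractions.get(c, 0.0) for c in CLASS_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")


def coverage_fraction(classmap: ClassMap, lake_mask: np.ndarray | None = None,
                      date: str | pd.Timestamp | None = None) -> CoverageRecord:
    """Class fractions over the valid lake pixels of one class map.

    ``lake_mask`` restricts the census to the lake (defaults to the map's
    own valid footprint); the denominator is the count of valid pixels
    inside it.
    """
    valid = classmap.valid
    if lake_mask is not None:
        lake_mask = np.asarray(lake_mask, dtype=bool)
        if lake_mask.shape != classmap.shape:
            raise ValueError(
                f"lake mask shape {lake_mask.shape} != class map shape {classmap.shape}"
            )
        valid = valid & lake_mask
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no valid lake pixels: empty mask or all-nodata map")
    fractions = {
        c: float((classmap.class_mask(c) & valid).sum() / n) for c in CLASS_NAMES
    }
    if date is None:
        date = classmap.provenance.get("date")
    if date is None:
        raise ValueError("no date: pass date= or set it in the class map provenance")
    ts = pd.Timestamp(date)
    return CoverageRecord(date=ts, season=season_of(ts), fractions=fractions,
                          valid_pixel_count=n)


def build_timeseries(records: list[CoverageRecord]) -> pd.DataFrame:
    """Long-format coverage table: year, season, class, fraction, valid_pixels.

    Sorted by year within season; a duplicate (year, season) is an error
    (two scenes for one window must be resolved upstream).  Missing
    combinations are simply absent rows, never zeros.
    """
    if not records:
        return pd.DataFrame(
            columns=["year", "season", "class", "fraction", "valid_pixels"]
        )
    keys = [(r.date.year, r.season) for r in records]
    dup = sorted({k for k in keys if keys.count(k) > 1})
    if dup:
        raise ValueError(f"duplicate (year, season) records: {dup}")
    rows = [
        {
            "year": r.date.year,
            "season": r.season,
            "class": c,
            "fraction": r.fractions[c],
            "valid_pixels": r.valid_pixel_count,
        }
        for r in records
        for c in CLASS_NAMES
    ]
    df = pd.DataFrame(rows)
    df["season"] = pd.Categorical(df["season"], categories=SEASONS, ordered=True)
    return df.sort_values(["season", "year", "class"], ignore_index=True)
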