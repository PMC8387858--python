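"""Age-band definitions and calendar arithmetic shared across the pipeline.

Five pre-defined age groups partition childhood: infancy (<1 year),
pre-school (1-4), primary school (5-9), middle school (10-13) and
adolescence (14-17).  Band boundaries fall on birthdays (ages 1, 5, 10,
14 and 18); all date intervals are half-open ``[start, end)`` so a
boundary day belongs to the older band and no day is double counted.
Person-years use the 365.25-day year.
"""

from __future__ import annotations

import pandas as pd

#: Band labels, youngest first.
AGE_BANDS: tuple[str, ...] = ("<1", "1-4", "5-9", "10-13", "14-17")

#: Birthday ages delimiting the bands: band i spans ages
#: [BAND_BOUNDARY_AGES[i], BAND_BOUNDARY_AGES[i + 1]).
BAND_BOUNDARY_AGES: tuple[int, ...] = (0, 1, 5, 10, 14, 18)

DAYS_PER_YEAR = 365.25

#: Exposure look-back: an MMI case up to 2 years (730 days) before a
#: band's start still exposes the child for that band.
LOOKBACK_DAYS = 730


def add_years_vec(dates: pd.Series, years: int) -> pd.Series:
    """Calendrical anniversary of every date in a datetime Series.

    A 29 February anniversary maps to 28 February in non-leap years,
    which keeps 18th-birthday computation deterministic.  Implemented on
    year/month/day components so it vectorises over whole cohorts.
    """
    dates = pd.to_datetime(dates)
    y = dates.dt.year + years
    m = dates.dt.month
    d = dates.dt.day
    leap = (y % 4 == 0) & ((y % 100 != 0) | (y % 400 == 0))
    d = d.where(~((m == 2) & (d == 29) & ~leap), 28)
    parts = pd.DataFrame({"year": y, "month": m, "day": d}).reset_index(drop=True)
    out = pd.to_datetime(parts)
    out.index = dates.index
    return out


def add_years(date: pd.Timestamp, years: int) -> pd.Timestamp:
    """Calendrical anniversary of one date (29 Feb -> 28 Feb off-leap-years)."""
    return add_years_vec(pd.Series([pd.Timestamp(date)]), years).iloc[0]


def birthday_boundaries(birth_date: pd.Timestamp) -> list[pd.Timestamp]:
    """The six band-boundary dates for one child (ages 0, 1, 5, 10, 14, 18)."""
    return [add_years(pd.Timestamp(birth_date), a) for a in BAND_BOUNDARY_AGES]


def person_years(start: pd.Timestamp, end: pd.Timestamp) -> float:
    """Length of the half-open interval [start, end) in 365.25-day years."""
    return (pd.Timestamp(end) - pd.Timestamp(start)).days / DAYS_PER_YEAR
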