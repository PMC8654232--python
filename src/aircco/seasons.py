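"""Asthma-season calendar.

Seasons here are *asthma seasons*: intra-annual periods of relative asthma
ED-visit burden, not astronomical or meteorological seasons.  The four
seasons partition the calendar year:

* winter: January 1 – February 28/29
* spring: March 1 – May 31
* summer: June 1 – August 19
* fall:   August 20 – December 31

The fall season starts at the approximate beginning of the school year and
contains the back-to-school visit surge.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "Season",
    "SEASONS",
    "SEASON_NAMES",
    "assign_season",
    "day_of_year_365",
    "season_doy_range",
    "season_day_count",
]


@dataclass(frozen=True)
class Season:
    """A (month, day)-delimited, year-agnostic slice of the calendar."""

    name: str
    start: tuple[int, int]  # inclusive (month, day)
    end: tuple[int, int]    # inclusive (month, day)

    def contains(self, date: dt.date) -> bool:
        md = (date.month, date.day)
        # Feb 29 sorts between (2, 28) and (3, 1) and lands in winter.
        return self.start <= md <= self.end or (
            self.name == "winter" and md == (2, 29)
        )


SEASONS: dict[str, Season] = {
    "winter": Season("winter", (1, 1), (2, 28)),
    "spring": Season("spring", (3, 1), (5, 31)),
    "summer": Season("summer", (6, 1), (8, 19)),
    "fall": Season("fall", (8, 20), (12, 31)),
}

SEASON_NAMES = tuple(SEASONS)


def assign_season(date) -> str:
    """Name of the asthma season containing ``date`` (total on valid dates)."""
    date = _as_date(date)
    for season in SEASONS.values():
        if season.contains(date):
            return season.name
    raise RuntimeError("unreachable: seasons partition the year")  # pragma: no cover


def day_of_year_365(date) -> int:
    """Day of year on a fixed 365-bin scale; Feb 29 shares bin 59 with Feb 28.

    Collapsing by day of year across leap and common years needs a common
    index; mapping the leap day onto Feb 28 keeps 365 bins with every
    (month, day) after February aligned across years.
    """
    date = _as_date(date)
    doy = date.timetuple().tm_yday
    if calendar.isleap(date.year) and doy >= 60:
        doy -= 1
    return doy


def season_doy_range(name: str) -> tuple[int, int]:
    """Inclusive (first, last) 365-scale day-of-year covered by a season."""
    season = SEASONS[name]
    ref_year = 2001  # any common year
    first = day_of_year_365(dt.date(ref_year, *season.start))
    last = day_of_year_365(dt.date(ref_year, *season.end))
    return first, last


def season_day_count(name: str, years) -> int:
    """Number of calendar days assigned to a season over the given years.

    Leap days count toward winter, so winter has 60 days in leap years.
    """
    season = SEASONS[name]
    total = 0
    for year in years:
        start = dt.date(year, *season.start)
        end = dt.date(year, *season.end)
        if name == "winter" and calendar.isleap(year):
            end = dt.date(year, 2, 29)
        total += (end - start).days + 1
    return total


def _as_date(date) -> dt.date:
    if isinstance(date, pd.Timestamp):
        return date.date()
    if isinstance(date, dt.datetime):
        return date.date()
    if isinstance(date, dt.date):
        return date
    return pd.Timestamp(date).date()
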