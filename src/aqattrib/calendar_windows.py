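"""Chinese-New-Year-relative calendar windows.

Every analysis window in this package is expressed as an inclusive range of
whole-day offsets from the Chinese New Year's day (CNY, offset 0) of a given
year.  Because CNY moves by up to three weeks between years on the Gregorian
calendar, multi-year aggregation is aligned on these offsets, never on
calendar dates.

CNY dates are configuration, not computed astronomy: the default calendar
ships the published lunar-calendar dates for the 2015-2020 study years.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping

__all__ = [
    "CalendarError",
    "CnyCalendar",
    "WindowSpec",
    "BEFORE_CNY",
    "CNY_WINDOW",
    "EXTENDED_LOCKDOWN",
    "TOTAL_LOCKDOWN",
    "DEFAULT_WINDOWS",
    "day_offset",
    "window_dates",
    "align_by_offset",
]


class CalendarError(KeyError):
    """A year is missing from (or invalid in) the CNY calendar."""


_DEFAULT_CNY_DATES: Dict[int, dt.date] = {
    2015: dt.date(2015, 2, 19),
    2016: dt.date(2016, 2, 8),
    2017: dt.date(2017, 1, 28),
    2018: dt.date(2018, 2, 16),
    2019: dt.date(2019, 2, 5),
    2020: dt.date(2020, 1, 25),
}


class CnyCalendar:
    """Mapping year -> Chinese New Year's day (the origin of all windows)."""

    def __init__(self, dates: Mapping[int, dt.date] | None = None) -> None:
        source = _DEFAULT_CNY_DATES if dates is None else dates
        self._dates: Dict[int, dt.date] = {}
        for year, date in source.items():
            if date.year != year:
                raise CalendarError(
                    f"CNY date {date.isoformat()} does not fall in year {year}"
                )
            if date.month not in (1, 2):
                raise CalendarError(
                    f"CNY date for {year} must fall in January or February, got {date}"
                )
            self._dates[int(year)] = date

    @property
    def years(self) -> tuple:
        return tuple(sorted(self._dates))

    def cny_date(self, year: int) -> dt.date:
        try:
            return self._dates[year]
        except KeyError:
            raise CalendarError(
                f"no CNY date configured for year {year}; "
                f"configured years: {sorted(self._dates)}"
            ) from None

    def __contains__(self, year: int) -> bool:
        return year in self._dates

    @classmethod
    def from_config(cls, mapping: Mapping[int, str]) -> "CnyCalendar":
        """Build from a {year: ISO-8601 date string} mapping (e.g. parsed YAML)."""
        return cls({int(y): dt.date.fromisoformat(str(d)) for y, d in mapping.items()})


@dataclass(frozen=True)
class WindowSpec:
    """An inclusive CNY-relative window: offsets ``start_offset..end_offset``."""

    name: str
    start_offset: int
    end_offset: int

    def __post_init__(self) -> None:
        if self.start_offset > self.end_offset:
            raise ValueError(
                f"window {self.name!r}: start_offset {self.start_offset} exceeds "
                f"end_offset {self.end_offset}"
            )

    @property
    def n_days(self) -> int:
        return self.end_offset - self.start_offset + 1

    @property
    def offsets(self) -> range:
        return range(self.start_offset, self.end_offset + 1)


# The four study windows (inclusive day labels relative to the CNY's day).
BEFORE_CNY = WindowSpec("BeforeCNY", -21, -8)
CNY_WINDOW = WindowSpec("CNY", -7, 10)
EXTENDED_LOCKDOWN = WindowSpec("ExtendedLockdown", 11, 42)
TOTAL_LOCKDOWN = WindowSpec("TotalLockdown", -1, 42)

DEFAULT_WINDOWS: Dict[str, WindowSpec] = {
    w.name: w for w in (BEFORE_CNY, CNY_WINDOW, EXTENDED_LOCKDOWN, TOTAL_LOCKDOWN)
}


def day_offset(date: dt.date, year: int, calendar: CnyCalendar | None = None) -> int:
    """Whole-day offset of ``date`` from the CNY's day of ``year`` (CNY itself is 0)."""
    calendar = calendar or CnyCalendar()
    return (date - calendar.cny_date(year)).days


def window_dates(
    year: int, spec: WindowSpec, calendar: CnyCalendar | None = None
) -> list:
    """Contiguous inclusive list of calendar dates covered by ``spec`` in ``year``."""
    calendar = calendar or CnyCalendar()
    cny = calendar.cny_date(year)
    return [cny + dt.timedelta(days=off) for off in spec.offsets]


def align_by_offset(
    years: Iterable[int], spec: WindowSpec, calendar: CnyCalendar | None = None
) -> Dict[int, Dict[int, dt.date]]:
    """Map each offset of ``spec`` to its calendar date in every requested year.

    Returns {offset: {year: date}}; this is the alignment used to average
    multi-year series at equal CNY-relative days.
    """
    calendar = calendar or CnyCalendar()
    years = list(years)
    cny = {y: calendar.cny_date(y) for y in years}
    return {
        off: {y: cny[y] + dt.timedelta(days=off) for y in years}
        for off in spec.offsets
    }
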