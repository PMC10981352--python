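"""Biological-period calendar for the annual cycle of a sedentary
central-place forager.

The annual cycle is partitioned into six tracking periods (nest building,
incubation, chick rearing, post fledging, post breeding, wintering), each a
fixed month/day range applied to every tracking year.  Dates falling in the
gaps between ranges belong to no period and are excluded from analysis.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

__all__ = [
    "BiologicalPeriod",
    "PeriodCalendar",
    "DEFAULT_PERIODS",
    "default_calendar",
    "PERIOD_ORDER",
]

PERIOD_ORDER = [
    "nest_building",
    "incubation",
    "chick_rearing",
    "post_fledging",
    "post_breeding",
    "wintering",
]


@dataclass(frozen=True)
class BiologicalPeriod:
    """A named month/day range, inclusive on both ends, within one year."""

    name: str
    start: tuple[int, int]  # (month, day)
    end: tuple[int, int]

    def contains(self, date: dt.date) -> bool:
        key = (date.month, date.day)
        return self.start <= key <= self.end

    def date_range(self, year: int) -> tuple[dt.date, dt.date]:
        return (
            dt.date(year, self.start[0], self.start[1]),
            dt.date(year, self.end[0], self.end[1]),
        )


DEFAULT_PERIODS = (
    BiologicalPeriod("nest_building", (3, 10), (4, 20)),
    BiologicalPeriod("incubation", (4, 27), (5, 14)),
    BiologicalPeriod("chick_rearing", (5, 21), (6, 16)),
    BiologicalPeriod("post_fledging", (7, 10), (8, 8)),
    BiologicalPeriod("post_breeding", (10, 5), (11, 3)),
    BiologicalPeriod("wintering", (11, 6), (12, 6)),
)


class PeriodCalendar:
    """An ordered, non-overlapping set of biological periods.

    Raises ``ValueError`` at construction if any two ranges overlap.
    """

    def __init__(self, periods=DEFAULT_PERIODS):
        periods = tuple(periods)
        for p in periods:
            if p.start > p.end:
                raise ValueError(f"period {p.name!r} starts after it ends")
        ordered = sorted(periods, key=lambda p: p.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"periods {a.name!r} and {b.name!r} overlap "
                    f"({a.end} >= {b.start})"
                )
        self.periods = ordered

    def __iter__(self):
        return iter(self.periods)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.periods]

    def __getitem__(self, name: str) -> BiologicalPeriod:
        for p in self.periods:
            if p.name == name:
                return p
        raise KeyError(name)

    def assign_period(self, date: dt.date) -> str | None:
        """Name of the period containing *date*, or ``None`` in a gap."""
        for p in self.periods:
            if p.contains(date):
                return p.name
        return None


def default_calendar() -> PeriodCalendar:
    return PeriodCalendar(DEFAULT_PERIODS)
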