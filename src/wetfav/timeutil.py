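"""Calendar machinery shared by all models.

Two native resolutions exist side by side: inundation is a two-monthly
(bimonthly) series of calendar blocks, soil moisture is daily.  Everything
here is plain month arithmetic on ``pandas`` timestamps; a bimonth "step" is
identified by the first day of its block.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "ALL_YEAR",
    "bimonth_range",
    "bimonth_index_of",
    "bimonth_start_of",
    "is_bimonth_index",
    "shift_months",
    "water_year_of",
]


@dataclasses.dataclass(frozen=True)
class Season:
    """An inclusive month window, possibly wrapping the year end.

    ``Season(11, 3)`` means November through March.  ``Season(1, 12)`` is the
    whole year.
    """

    start_month: int
    end_month: int

    def __post_init__(self) -> None:
        for m in (self.start_month, self.end_month):
            if not 1 <= m <= 12:
                raise ValueError(f"month out of range: {m}")

    @property
    def months(self) -> frozenset[int]:
        s, e = self.start_month, self.end_month
        if s <= e:
            return frozenset(range(s, e + 1))
        return frozenset(range(s, 13)) | frozenset(range(1, e + 1))

    def contains_month(self, month) -> "bool | np.ndarray":
        """Vectorised month membership (month may be an array)."""
        month = np.asarray(month)
        s, e = self.start_month, self.end_month
        if s <= e:
            return (month >= s) & (month <= e)
        return (month >= s) | (month <= e)

    def overlaps_block(self, start_month) -> "bool | np.ndarray":
        """Whether a 2-month block starting at ``start_month`` overlaps the window."""
        start_month = np.asarray(start_month)
        second = start_month % 12 + 1
        return self.contains_month(start_month) | self.contains_month(second)

    def widened(self, by: int = 1) -> "Season":
        """A window extended ``by`` months on each side (capped at year-round)."""
        if len(self.months) + 2 * by >= 12:
            return ALL_YEAR
        s = (self.start_month - 1 - by) % 12 + 1
        e = (self.end_month - 1 + by) % 12 + 1
        return Season(s, e)


ALL_YEAR = Season(1, 12)


def _month_number(ts: pd.Timestamp) -> int:
    return ts.year * 12 + (ts.month - 1)


def bimonth_range(start: "pd.Timestamp | str", periods: int, anchor_month: int = 1) -> pd.DatetimeIndex:
    """First days of ``periods`` consecutive 2-month calendar blocks.

    ``anchor_month`` fixes the block phase: with the default 1 the blocks are
    Jan-Feb, Mar-Apr, ...  ``start`` must be the first day of a block.
    """
    start = pd.Timestamp(start)
    if start.day != 1 or (start.month - anchor_month) % 2 != 0:
        raise ValueError(
            f"{start.date()} is not the first day of a 2-month block anchored at month {anchor_month}"
        )
    months = _month_number(start) + 2 * np.arange(periods)
    return pd.DatetimeIndex(
        [pd.Timestamp(year=m // 12, month=m % 12 + 1, day=1) for m in months]
    )


def bimonth_index_of(dates, origin: pd.Timestamp) -> np.ndarray:
    """0-based step index of each date within the bimonth grid starting at ``origin``.

    Dates before ``origin`` get negative indices.
    """
    dates = pd.DatetimeIndex(dates)
    m0 = _month_number(pd.Timestamp(origin))
    months = dates.year.to_numpy() * 12 + (dates.month.to_numpy() - 1)
    return np.floor_divide(months - m0, 2)


def bimonth_start_of(date: pd.Timestamp, anchor_month: int = 1) -> pd.Timestamp:
    """First day of the 2-month block containing ``date``."""
    date = pd.Timestamp(date)
    m = _month_number(date)
    m -= (m - (anchor_month - 1)) % 2
    return pd.Timestamp(year=m // 12, month=m % 12 + 1, day=1)


def is_bimonth_index(index: pd.DatetimeIndex) -> bool:
    """True if ``index`` is consecutive 2-month block starts."""
    if len(index) == 0:
        return True
    if (index.day != 1).any():
        return False
    months = index.year.to_numpy() * 12 + (index.month.to_numpy() - 1)
    return bool(np.all(np.diff(months) == 2))


def shift_months(dates, months: float) -> pd.DatetimeIndex:
    """Shift dates by a possibly fractional number of calendar months.

    Whole months use calendar arithmetic; a fractional remainder is converted
    at 30 days per month (so 4.5 months = 4 months + 15 days).
    """
    whole = math.floor(abs(months)) * (1 if months >= 0 else -1)
    frac_days = round((months - whole) * 30)
    dates = pd.DatetimeIndex(dates)
    out = dates + pd.DateOffset(months=whole)
    if frac_days:
        out = out + pd.Timedelta(days=frac_days)
    return pd.DatetimeIndex(out)


def water_year_of(dates) -> np.ndarray:
    """Water year (July 1 - June 30) labelled by its starting calendar year."""
    dates = pd.DatetimeIndex(dates)
    return dates.year.to_numpy() - (dates.month.to_numpy() < 7).astype(int)
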