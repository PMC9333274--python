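"""Wet/dry season calendar used throughout the package.

The Austral wet season covers November-April (high river discharge, high
variability in inshore water quality) and the dry season May-October. Season
membership of an observation is decided by the calendar month of its date.
For per-year visit bookkeeping the wet months of calendar year Y are
Jan-Apr and Nov-Dec of Y taken chronologically, so that every fully covered
calendar year holds exactly the specified number of wet- and dry-season visits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

WET_MONTHS: tuple[int, ...] = (11, 12, 1, 2, 3, 4)
DRY_MONTHS: tuple[int, ...] = (5, 6, 7, 8, 9, 10)

#: months in season order within one calendar year (chronological)
_SEASON_MONTHS = {
    "wet": (1, 2, 3, 4, 11, 12),
    "dry": (5, 6, 7, 8, 9, 10),
}

MAX_VISITS_PER_SEASON = 6 * 4  # weekly-ish cap: 4 slots per month, 6 months


def season_of(month: int) -> str:
    """Return ``"wet"`` for Nov-Apr months, ``"dry"`` for May-Oct."""
    return "wet" if month in WET_MONTHS else "dry"


def season_days(year: int, season: str) -> pd.DatetimeIndex:
    """All calendar days of ``season`` within calendar year ``year``, in order."""
    months = _SEASON_MONTHS[season]
    parts = [
        pd.date_range(
            start=pd.Timestamp(year=year, month=m, day=1),
            end=pd.Timestamp(year=year, month=m, day=1) + pd.offsets.MonthEnd(0),
            freq="D",
        )
        for m in months
    ]
    return parts[0].append(parts[1:])


def slot_bounds(n_days: int, n_slots: int) -> list[tuple[int, int]]:
    """Split ``n_days`` day indices into ``n_slots`` contiguous equal slots."""
    edges = np.floor(np.linspace(0, n_days, n_slots + 1)).astype(int)
    return [(int(edges[j]), int(edges[j + 1])) for j in range(n_slots)]


def slot_centers(year: int, season: str, n_slots: int) -> list[pd.Timestamp]:
    """Midpoint dates of ``n_slots`` evenly spaced slots in a season-year.

    Used both to anchor visit placement and as the target dates when thinning
    denser records back to a sparser cadence.
    """
    days = season_days(year, season)
    return [days[(lo + hi - 1) // 2] for lo, hi in slot_bounds(len(days), n_slots)]
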