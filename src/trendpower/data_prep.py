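"""Turn raw observations into analysis-ready series.

Pipeline order is fixed: average duplicate measurements, depth-average surface
and bottom, impute below-detection values (done upstream at 1/2DL), drop any
analyte-specific institution exclusions, then restrict to a time window and
log-transform. Also implements the design-scenario subsampling that thins the
post-2015 record back to the pre-2015 cadence (three visits per site-year).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seasons import season_of, slot_centers
from .synthetic_data import PRE2015_SITES

logger = logging.getLogger(__name__)

#: (analyte, project) pairs dropped by the default pipeline: NOx measurements
#: from the second institution are excluded because of analytical-method
#: differences that inter-institution validation could not reconcile.
DEFAULT_PROJECT_EXCLUSIONS: tuple[tuple[str, str], ...] = (("NOx", "JCU"),)


@dataclass(frozen=True)
class PeriodWindow:
    """A labelled time window with explicit bound inclusivity."""

    label: str
    start: pd.Timestamp | None
    end: pd.Timestamp | None
    start_inclusive: bool = False
    end_inclusive: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "start", None if self.start is None else pd.Timestamp(self.start)
        )
        object.__setattr__(
            self, "end", None if self.end is None else pd.Timestamp(self.end)
        )
        if self.start is not None and self.end is not None and self.end <= self.start:
            raise ValueError("window end must be after start")

    def contains(self, dates: pd.Series) -> pd.Series:
        mask = pd.Series(True, index=dates.index)
        if self.start is not None:
            mask &= dates >= self.start if self.start_inclusive else dates > self.start
        if self.end is not None:
            mask &= dates <= self.end if self.end_inclusive else dates < self.end
        return mask

    @property
    def span_days(self) -> float:
        if self.start is None or self.end is None:
            return float("inf")
        return float((self.end - self.start).days)


def standard_windows() -> dict[str, PeriodWindow]:
    """The four comparison windows, bounds encoded exactly as published.

    The three pre-2015 windows each cover roughly five years of the sparser
    original design, matched in length to the data available after the 2015
    re-design; the post-2015 window is open-ended on the right.
    """
    return {
        "pre-2015-S1": PeriodWindow(
            "pre-2015-S1", "2005-09-18", "2009-12-30", False, False
        ),
        "pre-2015-S2": PeriodWindow(
            "pre-2015-S2", "2010-06-15", "2015-01-01", True, False
        ),
        "pre-2015-S3": PeriodWindow(
            "pre-2015-S3", "2008-02-01", "2012-05-09", True, True
        ),
        "post-2015": PeriodWindow("post-2015", "2015-01-01", None, False, False),
    }


_SCENARIO_POLICIES = {
    "null": ("pre2015_sites", "pre2015_rate"),
    "null_plus_sites": ("all_sites", "pre2015_rate"),
    "null_plus_samples": ("pre2015_sites", "full_rate"),
    "current": ("all_sites", "full_rate"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the sites-versus-frequency decomposition.

    ``null`` keeps only the original sampling locations thinned to the
    original three-visits-per-year cadence; ``null_plus_sites`` adds the new
    locations at the old cadence; ``null_plus_samples`` keeps the old
    locations at the new frequency; ``current`` is the full post-2015 record.
    """

    label: str

    def __post_init__(self):
        if self.label not in _SCENARIO_POLICIES:
            raise ValueError(
                f"unknown scenario {self.label!r}; expected one of "
                f"{sorted(_SCENARIO_POLICIES)}"
            )

    @property
    def site_policy(self) -> str:
        return _SCENARIO_POLICIES[self.label][0]

    @property
    def frequency_policy(self) -> str:
        return _SCENARIO_POLICIES[self.label][1]


@dataclass
class PreparedSeries:
    """Analysis-ready per-analyte series for one study area and window.

    ``data`` rows carry the sampling date, elapsed days from the first
    observation in the window (the trend clock), days from January 1 of the
    first sampling year (the seasonal clock), the natural-log analyte value,
    and site and project labels.
    """

    data: pd.DataFrame
    analyte: str
    area: str
    window_label: str

    @property
    def n(self) -> int:
        return len(self.data)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(1, "area", self.area)
        out.insert(5, "analyte", self.analyte)
        out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)


def average_replicates(observations: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over duplicate measurements within each
    (site, date, analyte, depth) cell; all other columns pass through."""
    keys = ["area", "site", "project", "date", "analyte", "depth"]
    agg = observations.groupby(keys, as_index=False, sort=False).agg(
        value=("value", "mean"),
        detection_limit=("detection_limit", "first"),
        below_dl=("below_dl", "max"),
    )
    return agg


def depth_average(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the surface and bottom values per (site, date, analyte).

    A single available layer passes through unchanged. Duplicate rows per
    layer indicate that replicate averaging was skipped and are rejected.
    """
    keys = ["area", "site", "project", "date", "analyte"]
    layer_counts = table.groupby(keys + ["depth"], sort=False).size()
    if (layer_counts > 1).any():
        bad = layer_counts[layer_counts > 1].index[0]
        raise ValueError(
            f"multiple rows per depth layer at {bad}; average replicates first"
        )
    agg = table.groupby(keys, as_index=False, sort=False).agg(
        value=("value", "mean"),
        detection_limit=("detection_limit", "first"),
        below_dl=("below_dl", "max"),
    )
    return agg


def exclude_project(
    table: pd.DataFrame, analyte: str, project: str
) -> pd.DataFrame:
    """Drop all rows of one analyte measured by one institution."""
    drop = (table["analyte"] == analyte) & (table["project"] == project)
    if drop.any():
        logger.info(
            "excluding %d %s rows from project %s", int(drop.sum()), analyte, project
        )
    return table.loc[~drop].reset_index(drop=True)


def prepare_table(
    observations: pd.DataFrame,
    exclusions: tuple[tuple[str, str], ...] = DEFAULT_PROJECT_EXCLUSIONS,
) -> pd.DataFrame:
    """Replicate-average, depth-average and apply project exclusions."""
    table = depth_average(average_replicates(observations))
    for analyte, project in exclusions:
        table = exclude_project(table, analyte, project)
    return table


def prepare_series(
    table: pd.DataFrame, analyte: str, area: str, window: PeriodWindow
) -> PreparedSeries:
    """Restrict a prepared table to one analyte/area/window and log-transform.

    Elapsed days are measured from the earliest retained date; the seasonal
    clock from January 1 of that date's year, so the fitted seasonal curve is
    phased relative to January 1.
    """
    sel = table[(table["analyte"] == analyte) & (table["area"] == area)].copy()
    sel["date"] = pd.to_datetime(sel["date"])
    sel = sel[window.contains(sel["date"])]
    if sel.empty:
        raise ValueError(
            f"no {analyte} observations for {area} in window {window.label}"
        )
    bad = sel["value"] <= 0
    if bad.any():
        rows = sel.loc[bad, ["date", "site"]].head(5).to_dict("records")
        raise ValueError(f"non-positive values cannot be log-transformed: {rows}")
    sel = sel.sort_values(["date", "site"], kind="stable").reset_index(drop=True)
    t0 = sel["date"].min()
    origin = pd.Timestamp(year=t0.year, month=1, day=1)
    data = pd.DataFrame(
        {
            "date": sel["date"],
            "site": sel["site"],
            "project": sel["project"],
            "x_days": (sel["date"] - t0).dt.days.astype(float),
            "clock_days": (sel["date"] - origin).dt.days.astype(float),
            "log_value": np.log(sel["value"].to_numpy(float)),
        }
    )
    return PreparedSeries(data=data, analyte=analyte, area=area,
                          window_label=window.label)


def _thin_site_year(dates: pd.Series, year: int) -> set[pd.Timestamp]:
    """Pick 1 wet + 2 dry visits from one site-year, nearest to the slot
    midpoints of the sparse cadence; ties broken by the earlier date."""
    keep: set[pd.Timestamp] = set()
    months = pd.DatetimeIndex(dates).month
    for season, n_slots in (("wet", 1), ("dry", 2)):
        in_season = [d for d, m in zip(dates, months) if season_of(m) == season]
        targets = slot_centers(year, season, n_slots)
        available = sorted(set(in_season))
        for target in targets:
            if not available:
                break
            dists = np.array([abs((d - target).days) for d in available])
            best = np.flatnonzero(dists == dists.min())
            # exact distance ties between distinct dates are resolved by the
            # earlier date; available is sorted so index 0 of the tie wins
            chosen = available[int(best[0])]
            keep.add(chosen)
            available.remove(chosen)
    return keep


def subsample_scenario(
    post2015_table: pd.DataFrame, scenario: ScenarioSpec, seed: int = 0
) -> pd.DataFrame:
    """Down-sample a post-2015 prepared table to one decomposition scenario.

    Site policy ``pre2015_sites`` keeps only the ten original locations;
    frequency policy ``pre2015_rate`` thins each site-year to three visits
    (one wet, two dry), deterministically: the visit nearest each sparse-slot
    midpoint is kept, earlier date winning exact ties, so ``seed`` never
    affects the selection in practice (it is reserved for tie-breaking among
    identical dates, which deduplication removes). The result is always a row
    subset of the input.
    """
    table = post2015_table.copy()
    table["date"] = pd.to_datetime(table["date"])
    if scenario.site_policy == "pre2015_sites":
        table = table[table["site"].isin(PRE2015_SITES)]
    if scenario.frequency_policy == "pre2015_rate":
        keep_mask = pd.Series(False, index=table.index)
        visits = table[["site", "date"]].drop_duplicates()
        visits["year"] = visits["date"].dt.year
        for (site, year), grp in visits.groupby(["site", "year"], sort=True):
            if len(grp) < 3:
                warnings.warn(
                    f"site {site} year {year} has only {len(grp)} visits; "
                    "keeping all",
                    stacklevel=2,
                )
                kept = set(grp["date"])
            else:
                kept = _thin_site_year(grp["date"], int(year))
            keep_mask |= (table["site"] == site) & table["date"].isin(kept)
        table = table[keep_mask]
    return table.reset_index(drop=True)
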