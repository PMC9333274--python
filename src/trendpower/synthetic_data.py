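"""Synthetic monitoring-data generator.

Emulates the Great Barrier Reef inshore Marine Monitoring Program (MMP)
sampling calendars and the statistical structure of the seasonal-trend
regression the power analysis rests on: log-scale linear trend, annual
harmonic, site and institution (project) offsets, visit-level noise, optional
surface/bottom and duplicate structure, and below-detection-limit censoring.
Every downstream stage of the pipeline is testable against data generated
here, with no access to the program's raw database.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from ._seeds import child_rng
from .seasons import MAX_VISITS_PER_SEASON, season_days, slot_bounds

PERIOD_DAYS = 365.25  # average calendar-year length, the harmonic period T

OBSERVATION_COLUMNS = [
    "date",
    "area",
    "site",
    "project",
    "analyte",
    "depth",
    "replicate",
    "value",
    "detection_limit",
    "below_dl",
]


@dataclass(frozen=True)
class SiteGroup:
    """A set of sites sharing a visit cadence and institution(s).

    When several projects are listed, visits at each site are shared between
    them in rotation (the re-designed program splits site visits between two
    institutions), which keeps institution effects estimable alongside site
    effects.
    """

    sites: tuple[str, ...]
    project: str | tuple[str, ...]
    wet_visits_per_year: int
    dry_visits_per_year: int

    def __post_init__(self):
        if isinstance(self.project, str):
            object.__setattr__(self, "project", (self.project,))
        else:
            object.__setattr__(self, "project", tuple(self.project))
        if not self.project:
            raise ValueError("site group needs at least one project")


@dataclass(frozen=True)
class DesignSpec:
    """Declarative sampling calendar: who samples where, how often.

    ``wet_visits_per_year``/``dry_visits_per_year`` count sampling visits per
    site in the Nov-Apr wet and May-Oct dry season of each calendar year.
    """

    study_area: str
    site_groups: tuple[SiteGroup, ...]
    start_date: pd.Timestamp
    end_date: pd.Timestamp

    def __post_init__(self):
        object.__setattr__(self, "start_date", pd.Timestamp(self.start_date))
        object.__setattr__(self, "end_date", pd.Timestamp(self.end_date))
        if self.end_date <= self.start_date:
            raise ValueError("end_date must be after start_date")
        seen: set[str] = set()
        for g in self.site_groups:
            if g.wet_visits_per_year < 0 or g.dry_visits_per_year < 0:
                raise ValueError("visit counts must be non-negative")
            if g.wet_visits_per_year == 0 and g.dry_visits_per_year == 0:
                raise ValueError(
                    f"site group {g.sites}: at least one season needs visits"
                )
            if max(g.wet_visits_per_year, g.dry_visits_per_year) > MAX_VISITS_PER_SEASON:
                raise ValueError(
                    f"site group {g.sites}: more than {MAX_VISITS_PER_SEASON} "
                    "visits per season cannot be scheduled"
                )
            for s in g.sites:
                if s in seen:
                    raise ValueError(f"duplicate site label {s!r}")
                seen.add(s)

    @property
    def sites(self) -> tuple[str, ...]:
        return tuple(s for g in self.site_groups for s in g.sites)

    def to_yaml(self, path) -> None:
        payload = {
            "study_area": self.study_area,
            "start_date": str(self.start_date.date()),
            "end_date": str(self.end_date.date()),
            "site_groups": [
                {
                    "sites": list(g.sites),
                    "project": list(g.project),
                    "wet_visits_per_year": g.wet_visits_per_year,
                    "dry_visits_per_year": g.dry_visits_per_year,
                }
                for g in self.site_groups
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "DesignSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        groups = tuple(
            SiteGroup(
                sites=tuple(g["sites"]),
                project=g["project"],
                wet_visits_per_year=int(g["wet_visits_per_year"]),
                dry_visits_per_year=int(g["dry_visits_per_year"]),
            )
            for g in payload["site_groups"]
        )
        return cls(
            study_area=payload["study_area"],
            site_groups=groups,
            start_date=pd.Timestamp(payload["start_date"]),
            end_date=pd.Timestamp(payload["end_date"]),
        )


@dataclass(frozen=True)
class GeneratorParams:
    """Generating values for the log-scale seasonal-trend model.

    ``trend_delta`` is the fractional year-on-year change delta on the natural
    concentration scale (100*delta is the percentage change per year); it maps
    to a log-scale slope of ln(1+delta)/T per day so the back-transformed trend
    compounds exactly. ``sigma`` is the visit-level residual SD on the log
    scale; ``replicate_sd`` and ``depth_offset`` add within-visit structure the
    trend model itself does not fit (averaged away during preparation).
    """

    intercept: float = 0.0
    site_offsets: dict[str, float] = field(default_factory=dict)
    project_offset: float = 0.0
    trend_delta: float = 0.0
    seasonal_cos: float = 0.0
    seasonal_sin: float = 0.0
    sigma: float = 0.3
    replicate_sd: float = 0.0
    depth_offset: float = 0.0
    n_duplicates: int = 2
    detection_limit: float | None = None
    analyte: str = "chl_a"
    seed: int = 0

    def __post_init__(self):
        if self.sigma < 0 or self.replicate_sd < 0:
            raise ValueError("sigma and replicate_sd must be non-negative")
        if self.trend_delta <= -1:
            raise ValueError("trend_delta must exceed -1")
        if self.n_duplicates < 1:
            raise ValueError("need at least one duplicate per layer")
        if self.site_offsets and not any(v == 0.0 for v in self.site_offsets.values()):
            raise ValueError("site_offsets must include a reference site at 0")
        if self.detection_limit is not None and self.detection_limit <= 0:
            raise ValueError("detection_limit must be positive")

    def with_delta(self, delta: float) -> "GeneratorParams":
        return replace(self, trend_delta=delta)


def delta_to_slope(delta: float, period_days: float = PERIOD_DAYS) -> float:
    """Log-scale slope per day giving an exact 100*delta % change per year."""
    if delta <= -1:
        raise ValueError("delta must exceed -1")
    return float(np.log1p(delta)) / period_days


def build_design_calendar(spec: DesignSpec, seed: int) -> pd.DataFrame:
    """Lay out sampling visits (date, site, project) for a design.

    Each season of each calendar year intersecting the design period is split
    into evenly spaced slots, one visit per slot, with the day within the slot
    jittered uniformly. Every calendar year fully inside the period therefore
    holds exactly the specified wet and dry visit counts per site; partially
    covered years keep only the visits that fall inside the period.
    Deterministic for a fixed ``(spec, seed)`` regardless of iteration order.
    """
    rows = []
    for group in spec.site_groups:
        for site in group.sites:
            for year in range(spec.start_date.year, spec.end_date.year + 1):
                dates = []
                for season, k in (
                    ("wet", group.wet_visits_per_year),
                    ("dry", group.dry_visits_per_year),
                ):
                    if k == 0:
                        continue
                    days = season_days(year, season)
                    rng = child_rng(seed, "calendar", site, year, season)
                    for lo, hi in slot_bounds(len(days), k):
                        dates.append(days[int(rng.integers(lo, hi))])
                # institutions rotate over the year's visits in date order
                for i, date in enumerate(sorted(dates)):
                    if spec.start_date <= date <= spec.end_date:
                        project = group.project[i % len(group.project)]
                        rows.append((date, spec.study_area, site, project))
    if not rows:
        raise ValueError("design period holds no sampling events")
    out = pd.DataFrame(rows, columns=["date", "area", "site", "project"])
    return out.sort_values(["date", "site"], kind="stable").reset_index(drop=True)


def simulate_measurements(
    events: pd.DataFrame, params: GeneratorParams
) -> pd.DataFrame:
    """Realise raw grab-sample measurements for a visit calendar.

    Each visit yields surface and bottom Niskin layers with
    ``params.n_duplicates`` duplicate measurements per layer. The log-scale
    true value is intercept + site offset + project offset + trend + annual
    harmonic + N(0, sigma^2) shared across the visit; bottom layers add
    ``depth_offset`` and every duplicate adds independent N(0, replicate_sd^2).
    Reported concentration is the exponential. Elapsed time (trend clock) runs
    from the first visit; the seasonal clock runs from January 1 of the first
    sampling year. Deterministic for a fixed ``params.seed``.
    """
    if events.empty:
        raise ValueError("no sampling events to simulate")
    events = events.sort_values(["date", "site"], kind="stable").reset_index(drop=True)
    dates = pd.to_datetime(events["date"])
    t0 = dates.min()
    origin = pd.Timestamp(year=t0.year, month=1, day=1)
    x_days = (dates - t0).dt.days.to_numpy(float)
    clock_days = (dates - origin).dt.days.to_numpy(float)

    site_off = events["site"].map(lambda s: params.site_offsets.get(s, 0.0)).to_numpy()
    projects = events["project"].to_numpy()
    first_project = sorted(set(projects))[0]
    proj_off = np.where(projects == first_project, 0.0, params.project_offset)

    omega = 2 * np.pi * clock_days / PERIOD_DAYS
    mu = (
        params.intercept
        + site_off
        + proj_off
        + delta_to_slope(params.trend_delta) * x_days
        + params.seasonal_cos * np.cos(omega)
        + params.seasonal_sin * np.sin(omega)
    )
    rng = child_rng(params.seed, "measurements")
    visit_noise = rng.normal(0.0, params.sigma, size=len(events))

    n_visits = len(events)
    layers = ("surface", "bottom")
    frames = []
    for layer in layers:
        for rep in range(1, params.n_duplicates + 1):
            log_val = mu + visit_noise
            if layer == "bottom":
                log_val = log_val + params.depth_offset
            log_val = log_val + rng.normal(0.0, params.replicate_sd, size=n_visits)
            frames.append(
                pd.DataFrame(
                    {
                        "date": dates,
                        "area": events["area"],
                        "site": events["site"],
                        "project": events["project"],
                        "analyte": params.analyte,
                        "depth": layer,
                        "replicate": rep,
                        "value": np.exp(log_val),
                        "detection_limit": params.detection_limit
                        if params.detection_limit is not None
                        else np.nan,
                        "below_dl": 0,
                    }
                )
            )
    obs = pd.concat(frames, ignore_index=True)
    obs = obs.sort_values(
        ["date", "site", "depth", "replicate"], kind="stable"
    ).reset_index(drop=True)
    return obs[OBSERVATION_COLUMNS]


def apply_detection_limit(
    observations: pd.DataFrame, detection_limit: float
) -> pd.DataFrame:
    """Censor values below the instrument detection limit.

    Values strictly below the limit are flagged ``below_dl`` and stored as half
    the detection limit (the 1/2DL substitution the monitoring program
    reports); values at or above the limit pass through unchanged.
    """
    if detection_limit <= 0:
        raise ValueError("detection_limit must be positive")
    out = observations.copy()
    bdl = out["value"] < detection_limit
    out.loc[bdl, "value"] = detection_limit / 2.0
    out.loc[bdl, "below_dl"] = 1
    out["detection_limit"] = detection_limit
    return out


def write_observations(observations: pd.DataFrame, path) -> None:
    """Write an observation table as long-format CSV (dates ISO 8601)."""
    out = observations.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_observations(path) -> pd.DataFrame:
    """Read a long-format observation CSV (synthetic or real exports)."""
    obs = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in OBSERVATION_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    return obs[OBSERVATION_COLUMNS]


# --- packaged MMP designs -------------------------------------------------

#: monitoring period of the original design
_PRE2015_START, _PRE2015_END = "2005-02-01", "2014-12-31"
#: re-designed program: February 2015 through mid-2019
_POST2015_START, _POST2015_END = "2015-02-01", "2019-07-03"


def mmp_pre2015_design() -> dict[str, DesignSpec]:
    """The 2005-2014 MMP calendars: 10 sites, 1 wet + 2 dry visits/yr (AIMS)."""
    areas = {
        "Russell-Mulgrave": ("RM1", "RM7", "RM8"),
        "Tully": ("TUL3",),
        "Burdekin": ("BUR1", "BUR2", "BUR4"),
        "Mackay-Whitsunday": ("WHI0", "WHI1", "WHI4"),
    }
    return {
        area: DesignSpec(
            study_area=area,
            site_groups=(SiteGroup(sites, "AIMS", 1, 2),),
            start_date=_PRE2015_START,
            end_date=_PRE2015_END,
        )
        for area, sites in areas.items()
    }


def mmp_post2015_design() -> dict[str, DesignSpec]:
    """The 2015-2019 MMP calendars: 22 sites at region-specific frequencies.

    Russell-Mulgrave and Tully core sites are visited ten times a year (7 wet +
    3 dry) with visits shared between AIMS and JCU; RM1 at 3+2 (AIMS);
    Burdekin sites at 7 wet + 2 dry shared, except BUR10 (monthly, 6+6, AIMS);
    Whitsunday sites at 3 wet + 2 dry (AIMS).
    """
    shared = ("AIMS", "JCU")
    return {
        "Russell-Mulgrave": DesignSpec(
            study_area="Russell-Mulgrave",
            site_groups=(
                SiteGroup(("RM3", "RM7", "RM8", "RM10"), shared, 7, 3),
                SiteGroup(("RM1",), "AIMS", 3, 2),
            ),
            start_date=_POST2015_START,
            end_date=_POST2015_END,
        ),
        "Tully": DesignSpec(
            study_area="Tully",
            site_groups=(
                SiteGroup(
                    ("TUL2", "TUL3", "TUL5", "TUL6", "TUL8", "TUL10"),
                    shared, 7, 3,
                ),
            ),
            start_date=_POST2015_START,
            end_date=_POST2015_END,
        ),
        "Burdekin": DesignSpec(
            study_area="Burdekin",
            site_groups=(
                SiteGroup(("BUR1", "BUR2", "BUR4", "BUR7", "BUR13"), shared, 7, 2),
                SiteGroup(("BUR10",), "AIMS", 6, 6),
            ),
            start_date=_POST2015_START,
            end_date=_POST2015_END,
        ),
        "Mackay-Whitsunday": DesignSpec(
            study_area="Mackay-Whitsunday",
            site_groups=(
                SiteGroup(("WHI1", "WHI4", "WHI5", "WHI6", "WHI7"), "AIMS", 3, 2),
            ),
            start_date=_POST2015_START,
            end_date=_POST2015_END,
        ),
    }


PRE2015_SITES: tuple[str, ...] = tuple(
    s for spec in mmp_pre2015_design().values() for s in spec.sites
)
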