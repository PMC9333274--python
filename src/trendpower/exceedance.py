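"""Time-to-exceedance projections.

A sustained fractional change of delta per year compounds the analyte level
as m * (1+delta)^t after t years. These helpers compute how long a projected
trend takes to cross the empirical 10th (declines) or 90th (increases)
percentile of the recent record — the "how soon does the state change"
companion to the power analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

import scipy.stats as st


@dataclass
class ExceedanceResult:
    """Per-site and area-mean crossing times for one analyte and delta."""

    analyte: str
    area: str
    delta: float
    q10: float
    q90: float
    site_levels: pd.Series  # starting level m per site (natural scale)
    site_times: pd.Series  # years to cross the relevant bound
    mean_time: float

    def to_row(self) -> dict:
        key = "MEAN_TIME_Q90" if self.delta > 0 else "MEAN_TIME_Q10"
        return {
            "REGION": self.area,
            "DELTA": self.delta,
            "ANALYTE": self.analyte,
            key: self.mean_time,
        }


def percentile_bounds(values: np.ndarray) -> tuple[float, float]:
    """Empirical 10th and 90th percentiles (linear-interpolation quantiles)
    of prepared natural-scale values."""
    v = np.asarray(values, float)
    if v.size < 10:
        raise ValueError("need at least 10 values for stable percentile bounds")
    if np.any(v <= 0):
        raise ValueError("values must be positive")
    q10, q90 = np.quantile(v, [0.10, 0.90])
    return float(q10), float(q90)


def time_to_exceed(start_level: float, bound: float, delta: float) -> float:
    """Years for a level m compounding at (1+delta) per year to reach bound q:
    the exact solution t = ln(q/m)/ln(1+delta) of m (1+delta)^t = q.

    Returns 0 when the bound is already met or crossed in the trend's
    direction (q <= m for increases, q >= m for declines).
    """
    if delta == 0:
        raise ValueError("time to exceedance is undefined for delta = 0")
    if delta <= -1:
        raise ValueError("delta must exceed -1")
    if start_level <= 0 or bound <= 0:
        raise ValueError("levels must be positive")
    t = np.log(bound / start_level) / np.log1p(delta)
    return float(max(t, 0.0))


def area_exceedance(
    prepared: pd.DataFrame,
    analyte: str,
    area: str,
    delta: float,
    site_level: str = "geometric",
) -> ExceedanceResult:
    """Crossing times for one study area.

    Each site's starting level m is the geometric mean of its values (the
    central tendency matching the log-scale model; ``site_level="arithmetic"``
    is available). Percentile bounds come from the pooled area values; the
    relevant bound is the 90th percentile for increasing trends and the 10th
    for declines. The area summary is the arithmetic mean of per-site times.
    """
    sel = prepared[(prepared["analyte"] == analyte) & (prepared["area"] == area)]
    if sel.empty:
        raise ValueError(f"no {analyte} data for {area}")
    values = sel["value"].to_numpy(float)
    q10, q90 = percentile_bounds(values)
    if site_level == "geometric":
        levels = sel.groupby("site")["value"].apply(lambda v: st.gmean(v))
    elif site_level == "arithmetic":
        levels = sel.groupby("site")["value"].mean()
    else:
        raise ValueError(f"unknown site_level {site_level!r}")
    bound = q90 if delta > 0 else q10
    times = levels.apply(lambda m: time_to_exceed(float(m), bound, delta))
    return ExceedanceResult(
        analyte=analyte,
        area=area,
        delta=delta,
        q10=q10,
        q90=q90,
        site_levels=levels,
        site_times=times,
        mean_time=float(times.mean()),
    )


def exceedance_table(results: list[ExceedanceResult]) -> pd.DataFrame:
    """Assemble results as a REGION/DELTA/ANALYTE table with MEAN_TIME_Q10
    and MEAN_TIME_Q90 columns (one row per area x |delta| x analyte)."""
    rows: dict[tuple, dict] = {}
    for r in results:
        key = (r.area, abs(r.delta), r.analyte)
        row = rows.setdefault(
            key,
            {"REGION": r.area, "DELTA": abs(r.delta), "ANALYTE": r.analyte},
        )
        row["MEAN_TIME_Q90" if r.delta > 0 else "MEAN_TIME_Q10"] = r.mean_time
    out = pd.DataFrame(list(rows.values()))
    cols = ["REGION", "DELTA", "ANALYTE", "MEAN_TIME_Q10", "MEAN_TIME_Q90"]
    for c in cols:
        if c not in out.columns:
            out[c] = np.nan
    return out[cols]
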