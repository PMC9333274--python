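import numpy as np
import pandas as pd
import pytest

from trendpower import (
    DesignSpec,
    GeneratorParams,
    ModelSpec,
    PeriodWindow,
    PreparedSeries,
    SiteGroup,
    build_design_calendar,
    prepare_series,
    prepare_table,
    simulate_measurements,
)

#: unbounded window used when a test wants every simulated observation
OPEN_WINDOW = PeriodWindow("all", None, None)


def make_series(
    n: int = 60,
    years: float = 5.0,
    sigma: float = 0.6,
    intercept: float = 0.3,
    slope_per_day: float = 0.0,
    seasonal: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    start: str = "2015-01-15",
) -> PreparedSeries:
    """Single-site, single-project series built directly on the log scale."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(start, periods=n, freq=pd.Timedelta(days=years * 365.25 / n))
    x = (dates - dates[0]).days.astype(float)
    origin = pd.Timestamp(year=dates[0].year, month=1, day=1)
    clock = (dates - origin).days.astype(float)
    omega = 2 * np.pi * clock / 365.25
    y = (
        intercept
        + slope_per_day * x
        + seasonal[0] * np.cos(omega)
        + seasonal[1] * np.sin(omega)
        + rng.normal(0.0, sigma, n)
    )
    df = pd.DataFrame(
        {
            "date": dates,
            "site": "S1",
            "project": "AIMS",
            "x_days": x,
            "clock_days": clock,
            "log_value": y,
        }
    )
    return PreparedSeries(df, analyte="chl_a", area="TestArea", window_label="all")


def single_site_design(
    wet: int = 1, dry: int = 2, start: str = "2015-01-01", end: str = "2019-12-31"
) -> DesignSpec:
    return DesignSpec(
        "TestArea", (SiteGroup(("S1",), "AIMS", wet, dry),), start, end
    )


def simulate_prepared(
    design: DesignSpec,
    params: GeneratorParams,
    window: PeriodWindow = OPEN_WINDOW,
    calendar_seed: int = 0,
) -> PreparedSeries:
    """Calendar -> measurements -> prepared series, no exclusions."""
    cal = build_design_calendar(design, seed=calendar_seed)
    obs = simulate_measurements(cal, params)
    table = prepare_table(obs, exclusions=())
    return prepare_series(table, params.analyte, design.study_area, window)


@pytest.fixture(scope="session")
def small_series() -> PreparedSeries:
    return make_series(n=60, sigma=0.6, seed=11)


@pytest.fixture(scope="session")
def seasonal_fit_series() -> PreparedSeries:
    return make_series(
        n=120, sigma=0.4, slope_per_day=2e-4, seasonal=(0.3, -0.2), seed=7
    )
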