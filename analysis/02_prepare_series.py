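"""Prepare analysis-ready series from the raw observation table.

Averages duplicates and depth layers, drops the JCU NOx record, and splits
each analyte/area series into the four comparison windows (three ~5-year
pre-2015 periods and the post-2015 period), reporting the sample size the
trend model will see in each.
"""

from pathlib import Path

import pandas as pd

from trendpower.data_prep import prepare_series, prepare_table, standard_windows
from trendpower.pipeline import ANALYTES, AREAS, _NOX_EXCLUSIONS
from trendpower.synthetic_data import read_observations

OUTDIR = Path("results")


def main() -> None:
    obs = read_observations(OUTDIR / "observations.csv")
    table = prepare_table(obs, exclusions=_NOX_EXCLUSIONS)
    print(f"{len(obs)} raw measurements -> {len(table)} site-date values "
          "after replicate/depth averaging")

    rows = []
    for analyte in ANALYTES:
        for area in AREAS:
            for wlabel, window in standard_windows().items():
                try:
                    series = prepare_series(table, analyte, area, window)
                except ValueError:
                    continue
                rows.append({"analyte": analyte, "area": area,
                             "window": wlabel, "n": series.n})
    sizes = pd.DataFrame(rows)
    sizes.to_csv(OUTDIR / "series_sizes.csv", index=False)
    summary = sizes.groupby("window")["n"].agg(["min", "median", "max"])
    print("observations per analyte-area series, by window:")
    print(summary.to_string())
    print(f"wrote {OUTDIR/'series_sizes.csv'}")


if __name__ == "__main__":
    main()
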