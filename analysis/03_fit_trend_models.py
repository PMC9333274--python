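"""Fit the seasonal-trend regression and run residual diagnostics.

Fits the log-scale harmonic trend model per analyte/area/window with
classical, HAC and cluster-robust trend tests, then screens per-site fits
for residual AR(1) autocorrelation with Durbin-Watson statistics under 5%
false-discovery-rate control — the check that justifies resampling residuals
without block structure.
"""

from pathlib import Path

import pandas as pd

from trendpower.data_prep import (
    PreparedSeries,
    prepare_series,
    prepare_table,
    standard_windows,
)
from trendpower.harmonic_model import bh_fdr, durbin_watson, fit_ols
from trendpower.pipeline import ANALYTES, AREAS, _NOX_EXCLUSIONS, run_fit_summaries, validate_config
from trendpower.synthetic_data import read_observations

OUTDIR = Path("results")


def main() -> None:
    cfg = validate_config({"seed": 1})
    cfg.input_csv = str(OUTDIR / "observations.csv")
    fits = run_fit_summaries(cfg)
    fits.to_csv(OUTDIR / "fit_summaries.csv", index=False)
    classical = fits[fits["se_type"] == "classical"]
    print(f"fitted {len(classical)} analyte-area-window models "
          f"(median R^2 = {classical['r_squared'].median():.2f})")

    # per-site Durbin-Watson screen across analytes, post-2015 window
    obs = read_observations(OUTDIR / "observations.csv")
    table = prepare_table(obs, exclusions=_NOX_EXCLUSIONS)
    window = standard_windows()["post-2015"]
    records = []
    for analyte in ANALYTES:
        for area in AREAS:
            try:
                series = prepare_series(table, analyte, area, window)
            except ValueError:
                continue
            for site, grp in series.data.groupby("site"):
                if len(grp) < 12:
                    continue
                single = PreparedSeries(
                    grp.sort_values("date").reset_index(drop=True),
                    analyte, area, "post-2015",
                )
                try:
                    fit = fit_ols(single)
                except ValueError:
                    continue
                dw, p = durbin_watson(fit.residuals)
                records.append({"analyte": analyte, "area": area, "site": site,
                                "dw": dw, "p": p})
    diag = pd.DataFrame(records)
    diag["p_adjusted"] = bh_fdr(diag["p"])
    diag.to_csv(OUTDIR / "durbin_watson_screen.csv", index=False)
    n_reject = int((diag["p_adjusted"] < 0.05).sum())
    print(f"Durbin-Watson screen: {n_reject} of {len(diag)} site-analyte "
          "series show autocorrelation at FDR 5% "
          "(iid residual resampling is adequate when this stays small)")
    print(f"wrote {OUTDIR/'fit_summaries.csv'} and "
          f"{OUTDIR/'durbin_watson_screen.csv'}")


if __name__ == "__main__":
    main()
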