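#!/usr/bin/env python
"""Plot CNR versus mean glandular dose with the fitted root functions.

Reads results/experiment/dose_cnr_series.csv and draws each method's
measurements with its zero-intercept fit CNR = a sqrt(MGD), the standard
summary of a dose-CNR study.  Writes results/dose_cnr.png.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

import specmammo as sm

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    series_csv = ROOT / "experiment" / "dose_cnr_series.csv"
    if not series_csv.exists():
        raise SystemExit(f"{series_csv} missing - run analysis/02_run_experiment.py first")
    df = pd.read_csv(series_csv)

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, g in df.groupby("method", sort=False):
        series = sm.DoseCnrSeries(label, g["mgd_mgy"].to_numpy(), g["cnr"].to_numpy())
        a = sm.fit_root(series)
        grid = np.linspace(0, series.mgd_mgy.max() * 1.05, 200)
        pts = ax.plot(series.mgd_mgy, series.cnr, "o", label=f"{label} (a = {a:.1f})")
        ax.plot(grid, a * np.sqrt(grid), "-", color=pts[0].get_color(), alpha=0.7)
    ax.set_xlabel("mean glandular dose per pair [mGy]")
    ax.set_ylabel("CNR of the iodine tube")
    ax.legend()
    fig.tight_layout()
    out = ROOT / "dose_cnr.png"
    fig.savefig(out, dpi=150)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
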