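#!/usr/bin/env python
"""Cubic height-volume fits: the "all data" protocol and per-species
cross-application.

Fits one best cubic of each stand-height classification (H_max, H_mean,
H_100, Lorey's height) on stand volume over the pooled default-resource
summaries, then applies each all-data curve to every composition
separately (cross-application r^2 can be negative and is reported as
computed).  Requires results/default_sweep.csv from
02_default_resource_sweep.py.

Writes results/height_volume_r2.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from serasim import analysis, study

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    src = OUT / "default_sweep.csv"
    if not src.exists():
        sys.exit(f"{src} missing - run 02_default_resource_sweep.py first")
    df = pd.read_csv(src)
    fits = study.alldata_cubic_r2(df)
    rows = []
    for metric, fit in fits.items():
        rows.append({"dataset": "all_data", "height_class": metric,
                     "r2": fit.r2, "n": fit.n})
        for species, sub in df.groupby("species"):
            rows.append({"dataset": species, "height_class": metric,
                         "r2": analysis.r2_against_reference(fit, (
                             sub["volume_m3_per_ha"], sub[metric])),
                         "n": len(sub)})
    table = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "height_volume_r2.csv", index=False)
    wide = table.pivot(index="dataset", columns="height_class", values="r2")
    print(wide.round(3).to_string())
    best = wide.loc["all_data"].idxmax()
    print(f"\nbest all-data predictor of volume: {best}")
    print(f"wrote {OUT / 'height_volume_r2.csv'}")


if __name__ == "__main__":
    main()
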