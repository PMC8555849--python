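#!/usr/bin/env python
"""Predictive power against independent data vs model fit.

Compares the true skill statistic measured on the shared build test
partition (model fit) with the same models' skill on independently
sampled observation sets (dive, camera, ROV windows, unbiased class
inclusion, mode-aggregated and depth-screened). Forecast skill on
independent data is systematically lower than fit whenever the
independent campaign's sampling context differs from the build
campaign's. Writes results/ide_summary.csv.
"""

from pathlib import Path

import pandas as pd

METRICS = Path("results/experiment/metrics.csv")


def main() -> None:
    if not METRICS.exists():
        print("metrics table missing; running the experiment first...")
        import importlib

        importlib.import_module("03_weighting_experiment").main()
    results = pd.read_csv(METRICS)

    sub = results[
        (results.stratum == "all") & (results.metric.isin(["tss", "oa", "quantity"]))
        & (results.weighting == "prevalence")
    ]
    piv = (
        sub.pivot_table(index=["resolution", "dataset"], columns="metric", values="value")
        .round(3)
        .rename_axis(columns=None)
    )
    print("mean skill by dataset (prevalence-weighted models):\n")
    print(piv)

    tss = sub[sub.metric == "tss"].pivot_table(
        index=["seed", "resolution"], columns="dataset", values="value"
    )
    for ide in ("ide_dive", "ide_camera", "ide_rov"):
        if ide in tss:
            drop = (tss["test"] - tss[ide]).mean()
            print(f"\nmean TSS drop from fit to {ide[4:]}: {drop:+.3f}")

    out = Path("results/ide_summary.csv")
    piv.to_csv(out)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
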