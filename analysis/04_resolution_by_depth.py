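#!/usr/bin/env python
"""Resolution x depth interaction in model fit.

Summarizes, from the multi-seed experiment output, how the fine- and
coarse-resolution models compare across depth zones: the fine model
wins where substrate is patchy (shallow), the coarse model holds its
own or wins where the seafloor is smooth and survey artefacts dominate
the fine predictors (deep). Writes results/resolution_by_depth.csv.

Run analysis/03_weighting_experiment.py first (this script reruns it
if the metrics table is missing).
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
        (results.dataset == "test") & (results.stratum_type == "zone")
        & (results.weighting == "prevalence") & (results.metric == "oa")
    ]
    piv = sub.pivot_table(
        index=["seed", "stratum"], columns="resolution", values="value"
    ).dropna()
    piv["fine_minus_coarse"] = piv["fine"] - piv["coarse"]
    summary = (
        piv.groupby("stratum")["fine_minus_coarse"]
        .agg(mean="mean", n_seeds="count", fine_wins=lambda s: int((s > 0).sum()))
        .round(3)
    )
    order = ["0-5", "5-10", "10-20", "20-50", "50-100", "100-200", "200+"]
    summary = summary.reindex([z for z in order if z in summary.index])
    print("overall accuracy, fine minus coarse, by depth zone:\n")
    print(summary)
    out = Path("results/resolution_by_depth.csv")
    summary.to_csv(out)
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
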