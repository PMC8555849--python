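#!/usr/bin/env python
"""Figures: truth vs predicted maps, prevalence bars, importance heat map.

Renders, for seed 0, the substrate truth next to the weighted and
unweighted predicted class maps; observed vs predicted class
prevalence; and the relative variable importance (p/p_max) of every
model with fetch shown as missing for the coarse configuration.
PNGs go under results/figures/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from benthoscape.classify import predict_grid, relative_importance
from benthoscape.config import ExperimentConfig
from benthoscape.evalx import run_seed
from benthoscape.metrics import CLASSES

OUT = Path("results/figures")
CMAP = ListedColormap(["white", "#b2513e", "#c99e51", "#e8d9a0", "#7a8b6f"])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = ExperimentConfig()
    df, scene, models = run_seed(cfg, seed=0)

    # -- maps --------------------------------------------------------
    fig, axes = plt.subplots(1, 3, figsize=(13, 4.5))
    panels = [
        ("truth", scene.truth),
        ("weighted forest", predict_grid(models[("fine", "prevalence")], scene.stacks["fine"])),
        ("unweighted forest", predict_grid(models[("fine", "none")], scene.stacks["fine"])),
    ]
    for ax, (title, grid) in zip(axes, panels):
        ax.imshow(grid, cmap=CMAP, vmin=0, vmax=4, interpolation="nearest")
        ax.set_title(title)
        ax.set_xticks([])
        ax.set_yticks([])
    fig.suptitle("substrate class maps (fine resolution, seed 0)")
    fig.tight_layout()
    fig.savefig(OUT / "class_maps.png", dpi=130)

    # -- prevalence bars --------------------------------------------
    prev = df[
        (df.dataset == "test") & (df.stratum == "all") & (df.metric == "prevalence_l1")
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    piv = prev.pivot_table(index="resolution", columns="weighting", values="value")
    piv[["prevalence", "none"]].plot.bar(ax=ax, rot=0, color=["#4878b0", "#b0b0b0"])
    ax.set_ylabel("L1 distance, predicted vs observed prevalence")
    ax.legend(["weighted", "unweighted"])
    fig.tight_layout()
    fig.savefig(OUT / "prevalence_alignment.png", dpi=130)

    # -- importance heat map ----------------------------------------
    all_predictors = scene.stacks["fine"].names
    rows = {
        f"{res}/{arm}": relative_importance(m, all_predictors)
        for (res, arm), m in models.items()
    }
    imp = pd.DataFrame(rows).T[all_predictors]
    fig, ax = plt.subplots(figsize=(9, 3.5))
    im = ax.imshow(imp.to_numpy(dtype=float), cmap="coolwarm", vmin=0, vmax=1)
    ax.set_xticks(range(len(imp.columns)), imp.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(imp.index)), imp.index)
    for (i, j), v in np.ndenumerate(imp.to_numpy(dtype=float)):
        ax.text(j, i, "NA" if np.isnan(v) else f"{v:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, label="importance p/p_max")
    fig.tight_layout()
    fig.savefig(OUT / "variable_importance.png", dpi=130)

    print(f"wrote {len(list(OUT.glob('*.png')))} figures to {OUT}/")


if __name__ == "__main__":
    main()
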