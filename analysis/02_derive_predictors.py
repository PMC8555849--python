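#!/usr/bin/env python
"""Derive and export the predictor stacks at both analysis resolutions.

Writes every predictor layer (terrain derivatives, BPI scales, resampled
energy, fetch) for the seed-0 shelf as GeoTIFFs under
results/predictors/{fine,coarse}/, and prints per-layer summaries. The
fine ("regional") stack carries 11 layers including fetch; the coarse
("coastwide") stack 10, without fetch — wave exposure is not informative
at the depths the coarse model is trusted for.
"""

import json
from pathlib import Path

import numpy as np

from benthoscape.config import ExperimentConfig
from benthoscape.evalx import build_scene
from benthoscape.grids import write_grid

OUT = Path("results/predictors")


def main() -> None:
    cfg = ExperimentConfig()
    scene = build_scene(cfg, seed=0)
    for res, stack in scene.stacks.items():
        outdir = OUT / res
        outdir.mkdir(parents=True, exist_ok=True)
        geom = stack.geometry
        print(f"\n{res}: {geom.shape[0]}x{geom.shape[1]} cells at {geom.cell:.0f} m")
        print(f"{'layer':<12} {'min':>9} {'mean':>9} {'max':>9}")
        for name in stack.names:
            arr = stack[name]
            write_grid(geom.with_values(arr), outdir / f"{name}.tif")
            print(
                f"{name:<12} {np.nanmin(arr):9.3f} {np.nanmean(arr):9.3f} "
                f"{np.nanmax(arr):9.3f}"
            )
        (outdir / "manifest.json").write_text(
            json.dumps({"layers": stack.names, "cell_m": geom.cell}, indent=2)
        )
    print(f"\nwrote layers under {OUT}/")


if __name__ == "__main__":
    main()
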