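#!/usr/bin/env python
"""Simulate one synthetic shelf and its observation campaigns.

Writes bathymetry, substrate truth and the sampled build/independent
observations for seed 0 under results/scene/, and reports the realized
land fraction, map class prevalence, and the prevalence bias of the
build sample relative to the map — the imbalance the classifiers have
to cope with.
"""

import json
from pathlib import Path

import pandas as pd

from benthoscape.config import ExperimentConfig
from benthoscape.evalx import build_scene, child_seed
from benthoscape.grids import write_grid
from benthoscape.metrics import CLASSES, imbalance
from benthoscape.synth import CLASS_CODES, default_samplers, sample_observations

OUT = Path("results/scene")


def main() -> None:
    cfg = ExperimentConfig()
    scene = build_scene(cfg, seed=0)
    OUT.mkdir(parents=True, exist_ok=True)

    write_grid(scene.bathy_true, OUT / "bathymetry_true.tif")
    write_grid(scene.bathy, OUT / "bathymetry_measured.tif")
    write_grid(
        scene.bathy.with_values(scene.truth.astype(float)), OUT / "truth.tif",
        as_classes=True,
    )
    (OUT / "truth_classes.json").write_text(
        json.dumps({str(v): k for k, v in CLASS_CODES.items()} | {"0": "nodata"})
    )

    build_schemes, ide_schemes = default_samplers(
        cfg.n_build, cfg.n_ide, seed=child_seed(0, 5), rock_bias=cfg.rock_bias
    )
    obs = pd.concat(
        [sample_observations(scene.truth, scene.bathy_true, s) for s in build_schemes]
        + [
            sample_observations(scene.truth, scene.bathy_true, s, role="independent")
            for s in ide_schemes
        ],
        ignore_index=True,
    )
    obs.to_csv(OUT / "observations.csv", index=False)

    marine = scene.truth[scene.bathy_true.marine]
    map_prev = {c: float((marine == CLASS_CODES[c]).mean()) for c in CLASSES}
    build = obs[obs.role == "build"]
    sample_prev = build["class"].value_counts(normalize=True).reindex(CLASSES).fillna(0)

    print(f"shelf {scene.bathy.shape} cells at {scene.bathy.cell:.0f} m")
    print(f"land fraction: {scene.bathy_true.land.mean():.3f} (target {cfg.seafloor.land_fraction})")
    print(f"depth range: 0 to {scene.bathy_true.values.max():.0f} m")
    print("\nclass        map    build-sample")
    for c in CLASSES:
        print(f"{c:<8} {map_prev[c]:7.3f} {sample_prev[c]:11.3f}")
    print(f"\nimbalance: map {imbalance(list(map_prev.values())):.3f}, "
          f"build sample {imbalance(sample_prev.to_numpy()):.3f}")
    print(f"\nwrote scene to {OUT}/ ({len(obs)} observations)")


if __name__ == "__main__":
    main()
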