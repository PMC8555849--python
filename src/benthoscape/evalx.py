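"""Experiment orchestration on synthetic shelves.

Reproduces, at desk scale, the study design of the substrate-mapping
analysis: for each seed a synthetic shelf is generated, predictor
stacks are derived at a fine ("regional", fetch included) and a coarse
("coastwide", no fetch) resolution, biased build observations are
sampled and split 67/33, forests are fitted with and without
prevalence weighting at both resolutions on the same observations, and
all models are evaluated on the shared test partition (overall, by
depth zone, by region) and against independently sampled data sets
prepared by mode aggregation and depth screening.

Results come out as one tidy table: one row per
(seed, resolution, weighting, dataset, stratum, metric).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .classify import FittedModel, fit, predict_points
from .config import ExperimentConfig, RunManifest
from .grids import DepthGrid, PredictorStack, write_grid
from .metrics import CLASSES, aggregate_metrics, baselines, confusion
from .obsprep import aggregate_mode, assign_zone, join_predictors, screen_depth, split_build
from .synth import (
    SamplerScheme,
    SeafloorParams,
    TruthParams,
    bayes_rule,
    default_samplers,
    measure_bathymetry,
    sample_observations,
    simulate_bathymetry,
    simulate_truth,
)
from .terrain import block_mean, build_stack

__all__ = [
    "Scene",
    "child_seed",
    "synthesize_energy",
    "build_scene",
    "prepare_observations",
    "evaluate_model",
    "ide_evaluate",
    "run_seed",
    "run_experiment",
    "compare_weighting",
]

log = logging.getLogger("benthoscape")

_MIN_PER_ARM = {"prevalence", "none"}


def child_seed(base: int, k: int) -> int:
    """Deterministic sub-seed, kept below 2**31."""
    return (base * 1_000_003 + 7919 * k + 1) % (2**31)


def synthesize_energy(
    bathy: DepthGrid, seed: int, factor: int = 15
) -> tuple[DepthGrid, DepthGrid]:
    """Coarse tidal-speed and circulation grids over the shelf extent.

    Smooth lognormal-ish random fields at ``factor``-times coarser
    cells, standing in for averaged summer conditions from circulation
    models; they are later bilinearly resampled onto the analysis
    grids.
    """
    rng = np.random.default_rng(seed)
    nr = max(bathy.shape[0] // factor + 1, 4)
    nc = max(bathy.shape[1] // factor + 1, 4)

    def field(scale: float) -> DepthGrid:
        white = rng.standard_normal((nr, nc))
        smooth = ndimage.gaussian_filter(white, sigma=1.5, mode="reflect")
        smooth /= smooth.std()
        return DepthGrid(
            values=scale * np.exp(0.4 * smooth),
            x0=bathy.x0,
            y0=bathy.y0,
            cell=bathy.cell * factor,
        )

    return field(0.5), field(0.3)  # tide (m/s), circulation (m/s)


@dataclass
class Scene:
    """One synthetic shelf: true seafloor, measured stacks, truth, ceiling."""

    bathy_true: DepthGrid
    bathy: DepthGrid  # measured (with survey artefacts); what models see
    bathy_coarse: DepthGrid
    stacks: dict[str, PredictorStack]
    truth: np.ndarray
    bayes: np.ndarray  # optimal prediction under the generative model
    seafloor: SeafloorParams
    truthparams: TruthParams


def build_scene(config: ExperimentConfig, seed: int) -> Scene:
    """Simulate seafloor, energy, predictor stacks and truth for one seed.

    Substrate truth is generated from the *true* seafloor's predictor
    stack; the model stacks are derived from the *measured* bathymetry
    (true seafloor plus survey artefacts), at both resolutions. The
    coarse bathymetry is the block mean of the measured fine grid.
    """
    sf = dataclasses.replace(config.seafloor, seed=child_seed(seed, 1))
    tp = dataclasses.replace(config.truth, seed=child_seed(seed, 2))
    bathy_true = simulate_bathymetry(sf)
    tide, circ = synthesize_energy(bathy_true, child_seed(seed, 3))

    def regional(b: DepthGrid) -> PredictorStack:
        return build_stack(
            b,
            tide=tide,
            circulation=circ,
            bpi_specs=config.bpi_specs(),
            fetch_spec=config.fetch_spec(),
            resolution_class="regional",
        )

    stack_true = regional(bathy_true)
    truth = simulate_truth(bathy_true, tp, stack_true, decay_scale=sf.decay_scale)
    bayes = bayes_rule(bathy_true, tp, stack_true)

    bathy = measure_bathymetry(
        bathy_true, amplitude=config.artefact_amplitude, seed=child_seed(seed, 4)
    )
    fine = regional(bathy)
    bathy_coarse = block_mean(bathy, config.coarse_factor)
    coarse = build_stack(
        bathy_coarse,
        tide=tide,
        circulation=circ,
        bpi_specs=config.bpi_specs(),
        resolution_class="coastwide",
    )
    return Scene(
        bathy_true=bathy_true,
        bathy=bathy,
        bathy_coarse=bathy_coarse,
        stacks={"fine": fine, "coarse": coarse},
        truth=truth,
        bayes=bayes,
        seafloor=sf,
        truthparams=tp,
    )


def _assign_region(table: pd.DataFrame, bathy: DepthGrid, regions) -> pd.Series:
    """Region label per point from the configured west-east tiles."""
    frac = (table["x"].to_numpy() - bathy.x0) / (bathy.shape[1] * bathy.cell)
    out = np.full(len(table), "none", dtype=object)
    for name, (lo, hi) in regions.items():
        sel = (frac >= lo) & (frac < hi if hi < 1.0 else frac <= hi)
        out[sel] = name
    return pd.Series(out, index=table.index, name="region")


def prepare_observations(
    scene: Scene, config: ExperimentConfig, seed: int, manifest: RunManifest | None = None
) -> dict:
    """Sample build + independent observations and join both stacks.

    The build data are split 67/33 *before* the predictor join, so the
    fine and coarse models share one test partition (the same
    observations evaluated at both resolutions). Independent sets are
    mode-aggregated into fine cells and depth-screened at 50 m before
    the join, mirroring how quadrat data are prepared.
    """
    build_schemes, ide_schemes = default_samplers(
        n_build=config.n_build, n_ide=config.n_ide,
        seed=child_seed(seed, 5), rock_bias=config.rock_bias,
    )
    # sampling happens on the true seafloor: recorded depths are the
    # surveyors' point measurements, not the gridded product
    build = pd.concat(
        [sample_observations(scene.truth, scene.bathy_true, s) for s in build_schemes],
        ignore_index=True,
    )
    build["row_id"] = np.arange(len(build))
    train_raw, test_raw = split_build(build, 0.67, seed=child_seed(seed, 6))

    prepared: dict = {"train": {}, "test": {}, "ide": {}, "raw": build}
    for res, stack in scene.stacks.items():
        train, d1 = join_predictors(train_raw, stack)
        test, d2 = join_predictors(test_raw, stack)
        if manifest is not None:
            manifest.record_ledger(
                f"seed{seed}_join_{res}", len(train_raw) + len(test_raw),
                len(train) + len(test), d1 + d2,
            )
        prepared["train"][res] = train
        prepared["test"][res] = test

    for scheme in ide_schemes:
        raw = sample_observations(scene.truth, scene.bathy_true, scheme, role="independent")
        agg = aggregate_mode(raw, scene.bathy)
        screened, dropped = screen_depth(agg, scene.bathy, max_diff=50.0)
        if manifest is not None:
            manifest.record_ledger(
                f"seed{seed}_ide_{scheme.name}_screen", len(agg), len(screened), dropped
            )
        prepared["ide"][scheme.name] = {
            res: join_predictors(screened, stack)[0] for res, stack in scene.stacks.items()
        }
    return prepared


def _metric_records(observed, predicted, min_n: int, **keys) -> list[dict]:
    n = len(observed)
    if n < min_n:
        return [{**keys, "metric": "insufficient", "value": float(n)}]
    ms = aggregate_metrics(confusion(observed, predicted))
    return ms.to_records(**keys)


def evaluate_model(
    model: FittedModel,
    table: pd.DataFrame,
    *,
    min_n: int = 30,
    regions: dict | None = None,
    bathy: DepthGrid | None = None,
    **keys,
) -> list[dict]:
    """Metrics overall, per depth zone, and optionally per region."""
    pred = predict_points(model, table)
    obs = table["class"].to_numpy()
    records = _metric_records(obs, pred.to_numpy(), 1, stratum_type="all", stratum="all", **keys)

    # predicted-vs-observed prevalence distance (the weighting effect)
    p_obs = pd.Series(obs).value_counts(normalize=True).reindex(CLASSES, fill_value=0.0)
    p_pred = pred.value_counts(normalize=True).reindex(CLASSES, fill_value=0.0)
    records.append(
        {
            **keys, "stratum_type": "all", "stratum": "all",
            "metric": "prevalence_l1", "value": float(np.abs(p_obs - p_pred).sum()),
        }
    )

    zones = assign_zone(table["depth_m"].to_numpy())
    for zone in pd.unique(zones):
        sel = zones == zone
        records += _metric_records(
            obs[sel], pred.to_numpy()[sel], min_n, stratum_type="zone", stratum=zone, **keys
        )
    if regions is not None and bathy is not None:
        reg = _assign_region(table, bathy, regions).to_numpy()
        for name in pd.unique(reg):
            sel = reg == name
            records += _metric_records(
                obs[sel], pred.to_numpy()[sel], min_n, stratum_type="region", stratum=name, **keys
            )
    return records


def ide_evaluate(
    model: FittedModel, independent: pd.DataFrame, *, min_n: int = 30, **keys
) -> list[dict]:
    """Predictive-power metrics on an independent set, plus baseline-
    adjusted aggregates (metric minus its no-information value)."""
    records = evaluate_model(model, independent, min_n=min_n, **keys)
    tss0, tpr0, tnr0 = baselines(len(CLASSES))
    by_key = {
        (r["stratum_type"], r["stratum"], r["metric"]): r["value"] for r in records
    }
    adjusted = []
    for (stype, stratum, metric), value in by_key.items():
        base = {"tss": tss0, "oa": tpr0, "tnr_macro": tnr0}.get(metric)
        if base is not None:
            adjusted.append(
                {
                    **keys, "stratum_type": stype, "stratum": stratum,
                    "metric": f"{metric}_adj", "value": value - base,
                }
            )
    return records + adjusted


def run_seed(config: ExperimentConfig, seed: int, manifest: RunManifest | None = None):
    """Full pipeline for one seed; returns (tidy records, scene, models)."""
    scene = build_scene(config, seed)
    data = prepare_observations(scene, config, seed, manifest)
    records: list[dict] = []
    models: dict[tuple[str, str], FittedModel] = {}

    for res in scene.stacks:
        for arm in config.weighting_arms:
            spec = config.forest_spec(arm, child_seed(seed, 10))
            model = fit(data["train"][res], spec)
            models[(res, arm)] = model
            # guard: fit metrics never see training rows
            overlap = set(data["test"][res]["row_id"]) & set(data["train"][res]["row_id"])
            if overlap:
                raise RuntimeError("train/test partitions overlap")
            records += evaluate_model(
                model, data["test"][res],
                min_n=config.min_stratum_n, regions=config.regions, bathy=scene.bathy,
                seed=seed, resolution=res, weighting=arm, dataset="test",
            )
            records.append(
                {
                    "seed": seed, "resolution": res, "weighting": arm, "dataset": "train",
                    "stratum_type": "all", "stratum": "all",
                    "metric": "oob_error", "value": model.oob_error,
                }
            )
            for name, tables in data["ide"].items():
                records += ide_evaluate(
                    model, tables[res], min_n=config.min_stratum_n,
                    seed=seed, resolution=res, weighting=arm, dataset=f"ide_{name}",
                )

    # generative ceiling: the Bayes rule on the latent index, at the
    # same test points as the fine models
    test = data["test"]["fine"]
    row, col = scene.bathy.index_of(test["x"].to_numpy(), test["y"].to_numpy())
    from .synth import CODE_TO_CLASS

    pred = np.array([CODE_TO_CLASS.get(int(c), "Mud") for c in scene.bayes[row, col]])
    records += _metric_records(
        test["class"].to_numpy(), pred, 1,
        stratum_type="all", stratum="all",
        seed=seed, resolution="fine", weighting="bayes", dataset="test",
    )
    return pd.DataFrame.from_records(records), scene, models


def run_experiment(config: ExperimentConfig, outdir: str | Path | None = None) -> pd.DataFrame:
    """Run all configured seeds; write tidy CSVs, maps and a manifest.

    A failing seed is logged and skipped; it aborts that seed, not the
    run.
    """
    outdir = Path(outdir if outdir is not None else config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest.for_config(config, version=__version__)
    frames = []
    for seed in config.seeds:
        try:
            df, scene, models = run_seed(config, seed, manifest)
            frames.append(df)
        except Exception:
            log.exception("seed %d failed; skipping", seed)
            continue
        if seed == config.seeds[0]:
            for (res, arm), model in models.items():
                from .classify import predict_grid

                grid = scene.bathy if res == "fine" else scene.bathy_coarse
                pred = predict_grid(model, scene.stacks[res])
                path = outdir / f"map_seed{seed}_{res}_{arm}.tif"
                write_grid(grid.with_values(pred.astype(float)), path, as_classes=True)
                manifest.record_file(path)
            truth_path = outdir / f"truth_seed{seed}.tif"
            write_grid(
                scene.bathy.with_values(scene.truth.astype(float)), truth_path, as_classes=True
            )
            manifest.record_file(truth_path)
    if not frames:
        raise RuntimeError("every seed failed")
    results = pd.concat(frames, ignore_index=True)
    results_path = outdir / "metrics.csv"
    results.to_csv(results_path, index=False)
    manifest.record_file(results_path)
    deltas = compare_weighting(results)
    deltas_path = outdir / "weighting_deltas.csv"
    deltas.to_csv(deltas_path, index=False)
    manifest.record_file(deltas_path)
    manifest.write(outdir / "manifest.json")
    return results


def compare_weighting(results: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum metric deltas, weighted minus unweighted.

    One row per (seed, resolution, dataset, stratum, metric) present
    in both arms.
    """
    arms = set(results["weighting"].unique())
    if not _MIN_PER_ARM <= arms:
        missing = _MIN_PER_ARM - arms
        raise ValueError(f"missing weighting arm(s): {sorted(missing)}")
    keys = ["seed", "resolution", "dataset", "stratum_type", "stratum", "metric"]
    pivot = (
        results[results["weighting"].isin(_MIN_PER_ARM)]
        .pivot_table(index=keys, columns="weighting", values="value", aggfunc="first")
        .dropna(subset=["prevalence", "none"])
        .reset_index()
    )
    pivot["delta"] = pivot["prevalence"] - pivot["none"]
    return pivot[keys + ["delta"]]
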