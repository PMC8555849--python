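"""Experiment configuration (YAML) and run manifests.

A config file mirrors the experiment design: one ``synthetic:`` section
for the generator, sampler sections for build and independent
campaigns, the two weighting arms, the fine/coarse resolution pair, and
the seed list. Unknown keys are rejected with a field-level message so
typos never silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .classify import ForestSpec
from .synth import SeafloorParams, TruthParams
from .terrain import BpiSpec, FetchSpec

__all__ = ["ExperimentConfig", "load_config", "save_config", "RunManifest"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to re-run an experiment identically."""

    seafloor: SeafloorParams = SeafloorParams()
    truth: TruthParams = TruthParams()
    coarse_factor: int = 5  # fine:coarse cell ratio (20 m vs 100 m analogue)
    artefact_amplitude: float = 1.0  # survey-artefact noise sd (m) in measured bathymetry
    weighting_arms: tuple[str, ...] = ("prevalence", "none")
    n_trees: int = 200
    n_build: int = 4000
    n_ide: int = 1200
    rock_bias: float = 3.0
    bpi_radii: tuple[tuple[int, int], ...] = ((0, 5), (0, 12), (0, 30))
    fetch_bearings: int = 32
    fetch_cap: float = 6000.0
    regions: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"west": (0.0, 1 / 3), "center": (1 / 3, 2 / 3), "east": (2 / 3, 1.0)}
    )
    seeds: tuple[int, ...] = (0,)
    min_stratum_n: int = 30
    outdir: str = "results"

    def __post_init__(self) -> None:
        if self.coarse_factor < 2:
            raise ValueError("coarse cell size must be a multiple (>1) of fine")
        if not self.seeds:
            raise ValueError("need at least one seed")
        if not self.regions:
            raise ValueError("need at least one region")
        bad = set(self.weighting_arms) - {"prevalence", "none"}
        if bad:
            raise ValueError(f"unknown weighting arm(s): {sorted(bad)}")

    # -- derived specs ----------------------------------------------
    def bpi_specs(self) -> tuple[BpiSpec, ...]:
        labels = ("fine", "medium", "broad")
        return tuple(
            BpiSpec(inner, outer, lab)
            for (inner, outer), lab in zip(self.bpi_radii, labels)
        )

    def fetch_spec(self) -> FetchSpec:
        return FetchSpec(bearings=self.fetch_bearings, cap=self.fetch_cap)

    def forest_spec(self, weighting: str, seed: int) -> ForestSpec:
        return ForestSpec(n_trees=self.n_trees, weighting=weighting, seed=seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["seafloor"] = dataclasses.asdict(self.seafloor)
        d["truth"] = dataclasses.asdict(self.truth)
        return d


def _build_dataclass(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key == "seafloor":
            value = _build_dataclass(SeafloorParams, _tupled(value), f"{path}.seafloor")
        elif key == "truth":
            value = _build_dataclass(TruthParams, _tupled(value), f"{path}.truth")
        elif isinstance(value, list):
            value = _as_tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config at {path}: {exc}") from exc


def _as_tuple(value):
    return tuple(_as_tuple(v) if isinstance(v, list) else v for v in value)


def _tupled(d: dict) -> dict:
    return {k: _as_tuple(v) if isinstance(v, list) else v for k, v in d.items()}


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; defaults fill gaps."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    if "synthetic" in raw:  # accepted alias for the generator section
        raw["seafloor"] = raw.pop("synthetic")
    if "regions" in raw and isinstance(raw["regions"], dict):
        raw["regions"] = {k: tuple(v) for k, v in raw["regions"].items()}
    return _build_dataclass(ExperimentConfig, _tupled(raw), "config")


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


@dataclass
class RunManifest:
    """Reproducibility record written next to every experiment's outputs."""

    config_hash: str
    seeds: list[int]
    version: str
    ledgers: dict[str, dict[str, int]] = field(default_factory=dict)
    files: list[str] = field(default_factory=list)

    @classmethod
    def for_config(cls, config: ExperimentConfig, version: str) -> "RunManifest":
        blob = json.dumps(config.to_dict(), sort_keys=True).encode()
        return cls(
            config_hash=hashlib.sha256(blob).hexdigest()[:16],
            seeds=list(config.seeds),
            version=version,
        )

    def record_ledger(self, stage: str, rows_in: int, rows_out: int, dropped: int) -> None:
        if rows_in != rows_out + dropped:
            raise ValueError(
                f"ledger for {stage!r} does not reconcile: {rows_in} != {rows_out} + {dropped}"
            )
        self.ledgers[stage] = {"in": rows_in, "out": rows_out, "dropped": dropped}

    def record_file(self, path: str | Path) -> None:
        self.files.append(str(path))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))
        self.files.append(str(path))
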