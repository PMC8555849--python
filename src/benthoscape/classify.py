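"""Prevalence-weighted tree-ensemble substrate classification.

A thin, contract-enforcing wrapper around
:class:`sklearn.ensemble.RandomForestClassifier`: 1000 trees by
default, each grown on a with-replacement sample of 60% of the
training rows, Gini impurity importance, and optional per-class
weights ``w_c = 1 - N_c / N_total`` so that errors on rare classes
cost proportionally more in split selection and leaf votes.

Class labels are encoded to the fixed codes 1=Rock .. 4=Mud before
fitting, so prediction ties resolve deterministically toward the
lowest class code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .grids import PredictorStack
from .metrics import CLASSES
from .synth import CLASS_CODES, CODE_TO_CLASS

__all__ = [
    "ForestSpec",
    "FittedModel",
    "class_weights",
    "fit",
    "predict_points",
    "predict_grid",
    "relative_importance",
    "save_model",
    "load_model",
]

#: table columns that are never predictors
_META_COLS = ("x", "y", "depth_m", "class", "source", "role", "row_id")


@dataclass(frozen=True)
class ForestSpec:
    """Ensemble hyper-parameters (fixed across the analysis, not tuned)."""

    n_trees: int = 1000
    sample_fraction: float = 0.6
    weighting: str = "prevalence"  # "prevalence" | "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("need at least one tree")
        if not 0.0 < self.sample_fraction <= 1.0:
            raise ValueError("sample fraction must be in (0, 1]")
        if self.weighting not in ("prevalence", "none"):
            raise ValueError("weighting must be 'prevalence' or 'none'")


@dataclass
class FittedModel:
    """A trained ensemble plus its training bookkeeping."""

    estimator: RandomForestClassifier
    predictors: list[str]
    spec: ForestSpec
    class_counts: dict[str, int]
    oob_error: float
    importance: dict[str, float] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return sum(self.class_counts.values())


def class_weights(counts: dict[str, int] | pd.Series) -> dict[str, float]:
    """Prevalence weights ``w_c = 1 - N_c / N_total``.

    Rare classes get weights near 1, dominant classes near 0; a class
    holding all observations would get weight 0 (degenerate training).
    """
    counts = dict(counts)
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total count must be positive")
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    return {c: 1.0 - n / total for c, n in counts.items()}


def _predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def fit(train: pd.DataFrame, spec: ForestSpec = ForestSpec()) -> FittedModel:
    """Fit the ensemble on a prepared observation table.

    Every non-metadata column is a predictor, untransformed and
    unscreened for collinearity (tree ensembles are robust to
    non-normal, correlated predictors). Deterministic given the seed.
    """
    predictors = _predictor_columns(train)
    if not predictors:
        raise ValueError("no predictor columns in training table")
    X = train[predictors].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite predictor values in training table")
    y = train["class"].map(CLASS_CODES).to_numpy()
    observed = train["class"].value_counts()
    if observed.size < 2:
        raise ValueError("training data contain a single class")
    counts = {c: int(observed.get(c, 0)) for c in CLASSES}

    weight_arg = None
    if spec.weighting == "prevalence":
        w = class_weights({c: n for c, n in counts.items() if n > 0})
        weight_arg = {CLASS_CODES[c]: wc for c, wc in w.items()}

    est = RandomForestClassifier(
        n_estimators=spec.n_trees,
        criterion="gini",
        bootstrap=True,
        max_samples=spec.sample_fraction if spec.sample_fraction < 1.0 else None,
        oob_score=True,
        class_weight=weight_arg,
        random_state=spec.seed,
        n_jobs=1,
    )
    est.fit(X, y)
    importance = dict(zip(predictors, est.feature_importances_))
    return FittedModel(
        estimator=est,
        predictors=predictors,
        spec=spec,
        class_counts=counts,
        oob_error=float(1.0 - est.oob_score_),
        importance=importance,
    )


def predict_points(model: FittedModel, table: pd.DataFrame) -> pd.Series:
    """Predicted class per row (weighted majority vote of the trees)."""
    missing = [p for p in model.predictors if p not in table.columns]
    if missing:
        raise ValueError(f"table is missing predictor column(s): {missing}")
    if table.empty:
        return pd.Series([], dtype=object, index=table.index, name="predicted")
    X = table[model.predictors].to_numpy(dtype=float)
    codes = model.estimator.predict(X)
    return pd.Series(
        [CODE_TO_CLASS[int(c)] for c in codes], index=table.index, name="predicted"
    )


def predict_grid(model: FittedModel, stack: PredictorStack) -> np.ndarray:
    """Class-coded map over the stack's marine cells (0 = nodata).

    A cell is predicted only where every predictor layer is defined;
    the output nodata footprint is the union of the layers' nodata.
    """
    missing = [p for p in model.predictors if p not in stack]
    if missing:
        raise ValueError(f"stack is missing layer(s): {missing}")
    shape = stack.geometry.shape
    layers = [stack[p] for p in model.predictors]
    valid = ~np.logical_or.reduce([np.isnan(a) for a in layers])
    out = np.zeros(shape, dtype=np.uint8)
    if valid.any():
        X = np.column_stack([a[valid] for a in layers])
        out[valid] = model.estimator.predict(X).astype(np.uint8)
    return out


def relative_importance(
    model: FittedModel, all_predictors: list[str] | None = None
) -> dict[str, float]:
    """Gini importance scaled to the top predictor (p / p_max).

    Values lie in (0, 1] with exactly one predictor at 1. Predictors
    requested via ``all_predictors`` but absent from the model (e.g.
    fetch in the coastwide configuration) are reported as NaN.
    """
    imp = model.importance
    p_max = max(imp.values())
    rel = {k: (v / p_max if p_max > 0 else 0.0) for k, v in imp.items()}
    if all_predictors is not None:
        rel = {k: rel.get(k, float("nan")) for k in all_predictors}
    return rel


def save_model(model: FittedModel, path: str | Path) -> None:
    """Persist the ensemble (binary) with a JSON sidecar of its metadata."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    sidecar = {
        "version": 1,
        "predictors": model.predictors,
        "spec": {
            "n_trees": model.spec.n_trees,
            "sample_fraction": model.spec.sample_fraction,
            "weighting": model.spec.weighting,
            "seed": model.spec.seed,
        },
        "class_counts": model.class_counts,
        "oob_error": model.oob_error,
        "importance": model.importance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> FittedModel:
    path = Path(path)
    est = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FittedModel(
        estimator=est,
        predictors=meta["predictors"],
        spec=ForestSpec(**meta["spec"]),
        class_counts=meta["class_counts"],
        oob_error=meta["oob_error"],
        importance=meta["importance"],
    )
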