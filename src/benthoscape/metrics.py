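"""Multi-class map accuracy and error metrics.

Implements the evaluation suite used throughout the package: overall
accuracy, the multi-category true skill statistic (Peirce / Hanssen–
Kuipers skill score), per-class user and producer accuracies and true
negative rates, the Pontius-style decomposition of total disagreement
into quantity, exchange and shift components, a scalar prevalence
imbalance, and the no-information baselines of a uniformly random
predictor.

Matrix orientation is fixed package-wide: **rows = predicted class,
columns = observed class**, so user accuracy is row-wise and producer
accuracy column-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "ConfusionMatrix",
    "MetricSet",
    "confusion",
    "aggregate_metrics",
    "class_metrics",
    "imbalance",
    "baselines",
]

#: canonical substrate class order (also the tie-break priority order)
CLASSES: tuple[str, ...] = ("Rock", "Mixed", "Sand", "Mud")


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts with rows = predicted, columns = observed."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if c.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if c.sum() <= 0:
            raise ValueError("confusion matrix is empty")
        object.__setattr__(self, "counts", c.astype(np.int64))
        object.__setattr__(self, "labels", tuple(self.labels))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.labels)

    def proportions(self) -> np.ndarray:
        return self.counts / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


@dataclass
class MetricSet:
    """Aggregate and per-class metrics for one (model, dataset, stratum)."""

    n: int
    oa: float
    tss: float
    tnr_macro: float
    quantity: float
    exchange: float
    shift: float
    imbalance: float
    user: dict[str, float] = field(default_factory=dict)
    producer: dict[str, float] = field(default_factory=dict)
    tnr: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    def to_records(self, **keys: str) -> list[dict]:
        """Tidy (metric, value) records, one per scalar, tagged with keys."""
        rows = []
        for m, v in [
            ("n", self.n), ("oa", self.oa), ("tss", self.tss),
            ("tnr_macro", self.tnr_macro), ("quantity", self.quantity),
            ("exchange", self.exchange), ("shift", self.shift),
            ("imbalance", self.imbalance),
        ]:
            rows.append({**keys, "metric": m, "value": v})
        for cls in self.user:
            rows.append({**keys, "metric": f"user_{cls}", "value": self.user[cls]})
            rows.append({**keys, "metric": f"producer_{cls}", "value": self.producer[cls]})
            rows.append({**keys, "metric": f"tnr_{cls}", "value": self.tnr[cls]})
        return rows


def confusion(observed, predicted, labels=CLASSES) -> ConfusionMatrix:
    """Count (predicted i, observed j) pairs into a K x K matrix.

    Classes listed in ``labels`` but absent from the data keep zero
    rows/columns, so metrics stay comparable across strata.
    """
    observed = np.asarray(observed)
    predicted = np.asarray(predicted)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    k = len(labels)
    obs_i = pd.Categorical(observed.ravel(), categories=list(labels)).codes
    pred_i = pd.Categorical(predicted.ravel(), categories=list(labels)).codes
    if (obs_i < 0).any() or (pred_i < 0).any():
        bad = set(np.asarray(observed.ravel())[obs_i < 0]) | set(
            np.asarray(predicted.ravel())[pred_i < 0]
        )
        raise ValueError(f"unknown class label(s): {sorted(map(str, bad))}")
    counts = np.bincount(pred_i * k + obs_i, minlength=k * k).reshape(k, k)
    return ConfusionMatrix(counts=counts, labels=tuple(labels))


def class_metrics(cm: ConfusionMatrix) -> tuple[dict, dict, dict, list[str]]:
    """Per-class user accuracy, producer accuracy and one-vs-rest TNR.

    User accuracy conditions on prediction (row), producer on
    observation (column). A class never predicted (empty row) has
    undefined user accuracy; it is reported as 0.0 and flagged rather
    than dropped, and likewise for producer accuracy of an unobserved
    class.
    """
    c = cm.counts.astype(float)
    n = cm.n
    row = c.sum(axis=1)
    col = c.sum(axis=0)
    diag = np.diag(c)
    user: dict[str, float] = {}
    producer: dict[str, float] = {}
    tnr: dict[str, float] = {}
    flags: list[str] = []
    for i, lab in enumerate(cm.labels):
        if row[i] > 0:
            user[lab] = diag[i] / row[i]
        else:
            user[lab] = 0.0
            flags.append(f"user undefined (never predicted): {lab}")
        if col[i] > 0:
            producer[lab] = diag[i] / col[i]
        else:
            producer[lab] = 0.0
            flags.append(f"producer undefined (never observed): {lab}")
        # one-vs-rest collapse: negatives are all cells not observed as i
        neg = n - col[i]
        tn = n - row[i] - col[i] + diag[i]
        tnr[lab] = tn / neg if neg > 0 else 1.0
    return user, producer, tnr, flags


def imbalance(prevalences) -> float:
    """Normalized total-variation distance of class prevalence from uniform.

    ``0.5 * sum_j |p_j - 1/K| / (1 - 1/K)``: 0 for perfectly balanced
    classes, 1 when a single class holds everything.
    """
    p = np.asarray(prevalences, dtype=float)
    if (p < 0).any():
        raise ValueError("prevalences must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("prevalences must sum to 1")
    k = p.size
    return float(0.5 * np.abs(p - 1.0 / k).sum() / (1.0 - 1.0 / k))


def aggregate_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Aggregate accuracy/error metrics of a confusion matrix.

    With proportions ``p_ij`` (rows predicted, cols observed), row
    margins ``f_i`` and column margins ``o_j``:

    * overall accuracy ``OA = sum_i p_ii``,
    * multi-category true skill statistic
      ``TSS = (sum_i p_ii - sum_i f_i o_i) / (1 - sum_i o_i^2)``,
      which is 0 whenever predictions are independent of observations
      and reduces to sensitivity + specificity - 1 for two classes,
    * ``Quantity = 0.5 * sum_j |f_j - o_j|`` (margin mismatch),
    * ``Exchange = sum_{i<j} 2 min(p_ij, p_ji)`` (pairwise swaps),
    * ``Shift = (1 - OA) - Quantity - Exchange`` (residual
      reallocation), so the three components always sum to 1 - OA.
    """
    p = cm.proportions()
    f = p.sum(axis=1)  # predicted margins
    o = p.sum(axis=0)  # observed margins
    oa = float(np.trace(p))
    denom = 1.0 - float(o @ o)
    flags: list[str] = []
    if denom <= 0:
        tss = float("nan")
        flags.append("TSS undefined: single observed class")
    else:
        tss = float((np.trace(p) - f @ o) / denom)
    quantity = float(0.5 * np.abs(f - o).sum())
    exchange = float(2.0 * np.minimum(p, p.T)[np.triu_indices(cm.k, k=1)].sum())
    shift = (1.0 - oa) - quantity - exchange
    user, producer, tnr, cls_flags = class_metrics(cm)
    return MetricSet(
        n=cm.n,
        oa=oa,
        tss=tss,
        tnr_macro=float(np.mean(list(tnr.values()))),
        quantity=quantity,
        exchange=exchange,
        shift=shift,
        imbalance=imbalance(o),
        user=user,
        producer=producer,
        tnr=tnr,
        flags=flags + cls_flags,
    )


def baselines(k: int) -> tuple[float, float, float]:
    """No-information baselines (TSS0, TPR0, TNR0) for K classes.

    Under a uniformly random predictor the true skill statistic is 0,
    the expected one-vs-rest true positive rate is 1/K and the true
    negative rate 1 - 1/K (0.25 and 0.75 for four substrate classes).
    """
    if k < 2:
        raise ValueError("need at least 2 classes")
    return 0.0, 1.0 / k, 1.0 - 1.0 / k
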