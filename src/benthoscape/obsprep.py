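"""Observation preparation: from raw points to model-ready tables.

Observation tables are plain :class:`pandas.DataFrame` objects with the
columns ``x, y, depth_m, class, source, role`` (plus one column per
predictor after :func:`join_predictors`). Every operation that can drop
rows returns a ledger count alongside the table so row accounting
reconciles (rows in = rows out + dropped).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import DepthGrid, PredictorStack
from .metrics import CLASSES

__all__ = [
    "DEPTH_ZONES",
    "reclassify",
    "aggregate_mode",
    "screen_depth",
    "join_predictors",
    "split_build",
    "assign_zone",
]

#: ordered depth zones; upper bounds inclusive, intertidal = depth <= 0
DEPTH_ZONES: tuple[tuple[str, float, float], ...] = (
    ("Intertidal", -np.inf, 0.0),
    ("0-5", 0.0, 5.0),
    ("5-10", 5.0, 10.0),
    ("10-20", 10.0, 20.0),
    ("20-50", 20.0, 50.0),
    ("50-100", 50.0, 100.0),
    ("100-200", 100.0, 200.0),
    ("200+", 200.0, np.inf),
)

ZONE_ORDER: tuple[str, ...] = tuple(z[0] for z in DEPTH_ZONES)

#: tie-break priority for modal class assignment (rarer/harder first)
_PRIORITY: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}


def reclassify(
    table: pd.DataFrame, class_map: dict[str, str | None]
) -> tuple[pd.DataFrame, int]:
    """Map source-specific substrate labels onto the four model classes.

    ``class_map`` must resolve every label present: either to one of
    Rock/Mixed/Sand/Mud or to ``None`` (an explicit drop rule). An
    unmapped label is an error naming the label. Returns the mapped
    table and the number of dropped rows.
    """
    labels = table["class"].unique()
    unmapped = [lab for lab in labels if lab not in class_map]
    if unmapped:
        raise ValueError(f"unmapped substrate label(s): {sorted(map(str, unmapped))}")
    bad_targets = {v for v in class_map.values() if v is not None} - set(CLASSES)
    if bad_targets:
        raise ValueError(f"class map targets outside the four classes: {sorted(bad_targets)}")
    mapped = table["class"].map(class_map)
    keep = mapped.notna()
    out = table.loc[keep].copy()
    out["class"] = mapped[keep]
    return out, int((~keep).sum())


def aggregate_mode(table: pd.DataFrame, geometry: DepthGrid) -> pd.DataFrame:
    """Collapse quadrat/transect points to one record per occupied cell.

    The cell's record sits at the cell center, takes the modal class of
    the cell's points (ties broken by the fixed priority
    Rock > Mixed > Sand > Mud) and the mean of their recorded depths.
    Used for independent evaluation data; build data are deliberately
    *not* aggregated (duplicated predictors preserve sample size).
    """
    if table.empty:
        raise ValueError("cannot aggregate an empty observation table")
    row, col = geometry.index_of(table["x"].to_numpy(), table["y"].to_numpy())
    df = table.assign(_row=row, _col=col)

    def _collapse(group: pd.DataFrame) -> pd.Series:
        counts = group["class"].value_counts()
        top = counts.max()
        mode = min(counts[counts == top].index, key=_PRIORITY.__getitem__)
        r, c = group.name
        x, y = geometry.cell_center(np.array([r]), np.array([c]))
        return pd.Series(
            {
                "x": x[0],
                "y": y[0],
                "depth_m": group["depth_m"].mean(),
                "class": mode,
                "source": group["source"].iloc[0],
                "role": group["role"].iloc[0],
            }
        )

    out = (
        df.groupby(["_row", "_col"], sort=True)
        .apply(_collapse, include_groups=False)
        .reset_index(drop=True)
    )
    return out


def screen_depth(
    table: pd.DataFrame, bathy: DepthGrid, max_diff: float = 50.0
) -> tuple[pd.DataFrame, int]:
    """Drop rows whose recorded depth disagrees with the bathymetry.

    Removes rows where |recorded depth - bathymetry depth| exceeds
    ``max_diff`` metres (the screen applied to drop-camera positions,
    whose deflection grows with depth). Rows falling outside the grid
    are also removed. Returns the screened table and the removal count.
    """
    x = table["x"].to_numpy()
    y = table["y"].to_numpy()
    inside = bathy.contains(x, y)
    row, col = bathy.index_of(x, y)
    row = np.clip(row, 0, bathy.shape[0] - 1)
    col = np.clip(col, 0, bathy.shape[1] - 1)
    grid_depth = bathy.values[row, col]
    with np.errstate(invalid="ignore"):
        keep = inside & (np.abs(table["depth_m"].to_numpy() - grid_depth) <= max_diff)
    out = table.loc[keep].copy()
    return out, int(len(table) - len(out))


def join_predictors(
    table: pd.DataFrame, stack: PredictorStack
) -> tuple[pd.DataFrame, int]:
    """Attach one column per predictor layer, sampled at each point's cell.

    Multiple observations in one cell each keep their own row with
    identical (duplicated) predictor values, preserving the
    observational sample size. Observations landing on nodata cells
    (any layer) are dropped and counted.
    """
    sampled = stack.sample(table["x"].to_numpy(), table["y"].to_numpy())
    out = table.copy()
    for name, vals in sampled.items():
        out[name] = vals
    pred_cols = list(sampled)
    keep = out[pred_cols].notna().all(axis=1)
    return out.loc[keep].copy(), int((~keep).sum())


def split_build(
    table: pd.DataFrame, train_frac: float = 0.67, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simple random train/test partition of the build data.

    Unstratified, disjoint and exhaustive; the training partition gets
    ``round(n * train_frac)`` rows. Deterministic given the seed.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(n * train_frac))
    train = table.iloc[np.sort(perm[:n_train])].copy()
    test = table.iloc[np.sort(perm[n_train:])].copy()
    return train, test


def assign_zone(depth) -> np.ndarray | str:
    """Depth-zone label(s) for recorded depth(s) in metres.

    Intertidal for depth <= 0, then half-open zones with inclusive
    upper bounds: (0,5], (5,10], (10,20], (20,50], (50,100],
    (100,200], (200, inf).
    """
    arr = np.asarray(depth, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("depth must be finite")
    edges = [z[2] for z in DEPTH_ZONES[:-1]]  # 0, 5, 10, 20, 50, 100, 200
    idx = np.searchsorted(edges, arr, side="left")
    # searchsorted(left) maps depth == edge to that edge's zone (inclusive upper)
    labels = np.asarray(ZONE_ORDER, dtype=object)[idx]
    if arr.ndim == 0:
        return str(labels)
    return labels
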