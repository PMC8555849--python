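"""Seeded synthetic shelves: bathymetry, substrate truth, biased samplers.

The generator exists so that classifier skill can be measured against a
known generative process. It emulates the statistical structure a
substrate-mapping analysis assumes about a coastal shelf:

* a connected landmass with depth increasing seaward, shore-parallel
  ridge structure, and fine-scale terrain noise whose amplitude decays
  with depth (rough nearshore bottoms, sediment-smoothed deep shelf),
* substrate truth in four ordered classes (Rock > Mixed > Sand > Mud,
  ordered by seabed energy) obtained by thresholding a latent energy
  index built from rank-normalized fetch, tide, slope, and depth, plus
  unstructured noise whose standard deviation halves every
  ``decay_scale`` metres of depth — so substrate patchiness decays with
  depth while terrain noise does not,
* observation samplers with per-class inclusion bias and depth windows
  (grab data shallow and rock-biased; dive 0-20 m; camera 16-60 m; ROV
  deeper than ~20 m).

Everything is a pure function of its parameters including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grids import DepthGrid, PredictorStack
from .metrics import CLASSES

__all__ = [
    "SeafloorParams",
    "TruthParams",
    "SamplerScheme",
    "CLASS_CODES",
    "CODE_TO_CLASS",
    "simulate_bathymetry",
    "latent_index",
    "classify_index",
    "simulate_truth",
    "bayes_rule",
    "sample_observations",
    "default_samplers",
]

#: integer class codes used in truth/prediction grids (0 = nodata)
CLASS_CODES: dict[str, int] = {"Rock": 1, "Mixed": 2, "Sand": 3, "Mud": 4}
CODE_TO_CLASS: dict[int, str] = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class SeafloorParams:
    """Geometry and texture of a synthetic shelf.

    ``shelf_gradient`` is the mean seaward deepening in m per km;
    ``noise_amplitude`` is the standard deviation (m) of the fine
    terrain/measurement noise; ``decay_scale`` is the depth (m) at
    which fine-scale *substrate* patchiness halves.
    """

    shape: tuple[int, int] = (200, 200)
    cell: float = 25.0
    shelf_gradient: float = 40.0
    ridge_amplitude: float = 8.0
    noise_amplitude: float = 2.0
    decay_scale: float = 30.0
    land_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 16 or self.shape[1] < 16:
            raise ValueError("grid must be at least 16x16")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if not (0.0 <= self.land_fraction <= 0.5):
            raise ValueError("land fraction must be in [0, 0.5]")
        if self.decay_scale <= 0:
            raise ValueError("decay scale must be positive")


@dataclass(frozen=True)
class TruthParams:
    """Latent energy index weights, class thresholds, and noise levels."""

    w_fetch: float = 0.9
    w_tide: float = 0.5
    w_slope: float = 0.9
    w_depth: float = 1.6
    thresholds: tuple[float, float, float] = (-0.15, 0.10, 0.35)
    noise_sd: float = 0.12
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        t1, t2, t3 = self.thresholds
        if not (t1 < t2 < t3):
            raise ValueError("thresholds must be strictly increasing")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label noise must be in [0, 0.5)")


@dataclass(frozen=True)
class SamplerScheme:
    """One observation campaign: depth window, class bias, sample size."""

    name: str
    depth_window: tuple[float, float]
    bias: dict[str, float] = field(default_factory=lambda: {c: 1.0 for c in CLASSES})
    n: int = 1000
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.depth_window
        if not lo < hi:
            raise ValueError("depth window min must be < max")
        if self.n <= 0:
            raise ValueError("n must be positive")
        if any(v <= 0 for v in self.bias.values()):
            raise ValueError("bias multipliers must be positive")


def simulate_bathymetry(params: SeafloorParams) -> DepthGrid:
    """Generate a shelf-like depth grid with a connected coastal landmass.

    Depth (positive down) increases seaward (down-grid) on average;
    the landmass occupies roughly ``land_fraction`` of the grid along
    the northern edge and carries elevations above chart datum rather
    than nodata. With ridge and noise amplitudes zero the profile is a
    plane, strictly deepening seaward.
    """
    rng = np.random.default_rng(params.seed)
    nr, nc = params.shape
    rows = np.arange(nr)[:, None] + 0.5
    cols = np.arange(nc)[None, :] + 0.5

    grad_per_cell = params.shelf_gradient / 1000.0 * params.cell
    shore_row = params.land_fraction * nr
    base = grad_per_cell * (rows - shore_row) * np.ones((1, nc))

    # shore-parallel and oblique ridge undulation with random phases
    lam_r = nr / rng.uniform(2.0, 4.0)
    lam_c = nc / rng.uniform(2.0, 4.0)
    ph = rng.uniform(0, 2 * np.pi, size=3)
    ridge = params.ridge_amplitude * (
        0.6 * np.sin(2 * np.pi * cols / lam_c + ph[0])
        + 0.4 * np.sin(2 * np.pi * (rows + cols) / lam_r + ph[1])
        * np.cos(2 * np.pi * rows / lam_r + ph[2])
    )

    # fine terrain noise: smoothed white field whose amplitude is
    # noise_amplitude at the shoreline and halves every decay_scale
    # metres of depth (sediment infill smooths the deep shelf)
    white = rng.standard_normal((nr, nc))
    smooth = ndimage.gaussian_filter(white, sigma=1.5, mode="reflect")
    smooth /= smooth.std()
    depth_base = np.clip(base + ridge, 0.0, None)
    noise = params.noise_amplitude * np.power(2.0, -depth_base / params.decay_scale) * smooth

    depth = base + ridge + noise
    # keep the landmass connected: never let ridge/noise flood the top rows
    depth[rows[:, 0] < shore_row * 0.5, :] = np.minimum(
        depth[rows[:, 0] < shore_row * 0.5, :], -0.5
    )
    return DepthGrid(values=depth, x0=0.0, y0=nr * params.cell, cell=params.cell)


def measure_bathymetry(
    bathy: DepthGrid, amplitude: float = 1.0, seed: int = 0
) -> DepthGrid:
    """Corrupt a true seafloor with survey artefacts.

    Real gridded bathymetries carry track-line and interpolation
    artefacts that do not vanish offshore; substrate responds to the
    true terrain while classifiers only ever see the measured one.
    Adds a smoothed noise field of the given amplitude (m, sd) to
    marine cells; land elevations are left untouched. ``amplitude=0``
    returns the grid unchanged (a perfect survey).
    """
    if amplitude == 0:
        return bathy
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(bathy.shape)
    smooth = ndimage.gaussian_filter(white, sigma=1.0, mode="reflect")
    smooth /= smooth.std()
    values = bathy.values + np.where(bathy.marine, amplitude * smooth, 0.0)
    return bathy.with_values(values)


def _rank_normalize(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Map a layer to (0, 1) by rank over the masked cells."""
    out = np.full(values.shape, np.nan)
    v = values[mask]
    out[mask] = stats.rankdata(v) / (v.size + 1)
    return out


def latent_index(bathy: DepthGrid, tp: TruthParams, energy: PredictorStack) -> np.ndarray:
    """Noise-free latent energy index E over marine cells.

    ``E = w_f z(fetch) + w_t z(tide) + w_s z(slope) - w_d z(depth)``
    with each ``z`` the rank-normalized layer centered at 0.5, so high
    E means an energetic, scoured seabed (Rock) and low E a quiescent,
    depositional one (Mud).
    """
    if not energy.geometry.same_geometry(bathy):
        raise ValueError("energy stack is not co-registered with the bathymetry")
    for layer in ("fetch", "tide", "slope"):
        if layer not in energy:
            raise ValueError(f"energy stack is missing layer {layer!r}")
    marine = bathy.marine
    z = {
        name: _rank_normalize(energy[name], marine & ~np.isnan(energy[name]))
        for name in ("fetch", "tide", "slope")
    }
    z["depth"] = _rank_normalize(bathy.values, marine)
    e = (
        tp.w_fetch * (z["fetch"] - 0.5)
        + tp.w_tide * (z["tide"] - 0.5)
        + tp.w_slope * (z["slope"] - 0.5)
        - tp.w_depth * (z["depth"] - 0.5)
    )
    e[~marine] = np.nan
    return e


def classify_index(e: np.ndarray, thresholds: tuple[float, float, float]) -> np.ndarray:
    """Threshold the latent index into class codes (1=Rock .. 4=Mud)."""
    t1, t2, t3 = thresholds
    codes = np.where(
        np.isnan(e), 0, 4 - np.digitize(np.nan_to_num(e, nan=-np.inf), [t1, t2, t3])
    )
    codes[np.isnan(e)] = 0
    return codes.astype(np.uint8)


def simulate_truth(
    bathy: DepthGrid,
    tp: TruthParams,
    energy: PredictorStack,
    decay_scale: float = 30.0,
) -> np.ndarray:
    """Substrate truth grid: latent index + depth-decaying noise + label noise.

    The unstructured noise added to the latent index has standard
    deviation ``noise_sd * 2**(-depth / decay_scale)``, so fine-scale
    substrate patchiness halves every ``decay_scale`` metres of depth.
    Label noise then flips each cell to a uniformly random *other*
    class with the stated probability. Returns uint8 codes, 0 = nodata.
    """
    rng = np.random.default_rng(tp.seed)
    e = latent_index(bathy, tp, energy)
    marine = bathy.marine
    depth = np.clip(bathy.values, 0.0, None)
    sd = tp.noise_sd * np.power(2.0, -depth / decay_scale)
    e_noisy = e + sd * rng.standard_normal(e.shape)
    codes = classify_index(e_noisy, tp.thresholds)

    if tp.label_noise > 0:
        flip = (rng.random(codes.shape) < tp.label_noise) & marine
        offset = rng.integers(1, 4, size=codes.shape)  # 1..3: any other class
        codes = np.where(flip, (codes - 1 + offset) % 4 + 1, codes).astype(np.uint8)
    codes[~marine] = 0
    return codes


def bayes_rule(bathy: DepthGrid, tp: TruthParams, energy: PredictorStack) -> np.ndarray:
    """Optimal prediction under the generative model: threshold the
    noise-free latent index. Skill of any fitted classifier is bounded
    by this rule's skill (up to sampling noise)."""
    return classify_index(latent_index(bathy, tp, energy), tp.thresholds)


def sample_observations(
    truth: np.ndarray,
    bathy: DepthGrid,
    scheme: SamplerScheme,
    role: str = "build",
) -> pd.DataFrame:
    """Draw biased point observations of the truth grid.

    Cells eligible for sampling are marine cells whose depth lies in
    the scheme's window; a cell's inclusion probability is proportional
    to the bias multiplier of its true class. Sampling is with
    replacement (revisits are real: surveys resample good ground).
    Positions are jittered by a Gaussian offset and clipped back to the
    drawn cell when the jitter would leave the marine window. The
    recorded class and depth are those of the drawn cell, so recorded
    classes inherit only the truth grid's label noise.
    """
    rng = np.random.default_rng(scheme.seed)
    lo, hi = scheme.depth_window
    eligible = bathy.marine & (bathy.values > lo) & (bathy.values <= hi) & (truth > 0)
    idx = np.flatnonzero(eligible)
    if idx.size == 0:
        raise ValueError(
            f"sampler {scheme.name!r}: no eligible cells in depth window ({lo}, {hi}]"
        )
    codes = truth.ravel()[idx]
    weights = np.array([scheme.bias[CODE_TO_CLASS[c]] for c in codes])
    weights = weights / weights.sum()
    draws = rng.choice(idx.size, size=scheme.n, replace=True, p=weights)
    cells = idx[draws]
    row, col = np.unravel_index(cells, bathy.shape)
    x, y = bathy.cell_center(row, col)

    if scheme.jitter_sd > 0:
        jx = x + rng.normal(0, scheme.jitter_sd, size=x.size)
        jy = y + rng.normal(0, scheme.jitter_sd, size=y.size)
        jr, jc = bathy.index_of(jx, jy)
        nr, nc = bathy.shape
        inside = (jr >= 0) & (jr < nr) & (jc >= 0) & (jc < nc)
        ok = inside.copy()
        ok[inside] = eligible[jr[inside], jc[inside]] & (
            jr[inside] == row[inside]
        ) & (jc[inside] == col[inside])
        # jitter that stays inside the drawn cell is kept; otherwise clip back
        x = np.where(ok, jx, x)
        y = np.where(ok, jy, y)

    return pd.DataFrame(
        {
            "x": x,
            "y": y,
            "depth_m": bathy.values[row, col],
            "class": [CODE_TO_CLASS[c] for c in truth[row, col]],
            "source": scheme.name,
            "role": role,
        }
    )


def default_samplers(
    n_build: int = 4000, n_ide: int = 1200, seed: int = 0, rock_bias: float = 3.0
) -> tuple[list[SamplerScheme], list[SamplerScheme]]:
    """Build and independent-evaluation sampler suites.

    The build suite mimics hydrographic-survey bias: a large grab
    campaign biased shallow and towards Rock, a dive campaign in the
    top 20 m, and a deeper ROV campaign. The independent suite uses
    dive (0-20 m), camera (16-60 m) and ROV (>20 m) windows with
    unbiased class inclusion.
    """
    rock = {**{c: 1.0 for c in CLASSES}, "Rock": rock_bias}
    flat = {c: 1.0 for c in CLASSES}
    build = [
        SamplerScheme("grab", (0.0, 50.0), rock, int(n_build * 0.6), seed=seed * 7 + 1),
        SamplerScheme("dive", (0.0, 20.0), rock, int(n_build * 0.15), seed=seed * 7 + 2),
        SamplerScheme("rov", (20.0, 700.0), flat, int(n_build * 0.25), seed=seed * 7 + 3),
    ]
    ide = [
        SamplerScheme("dive", (0.0, 20.0), flat, int(n_ide * 0.4), seed=seed * 7 + 4),
        SamplerScheme("camera", (16.0, 60.0), flat, int(n_ide * 0.3), seed=seed * 7 + 5),
        SamplerScheme("rov", (20.0, 700.0), flat, int(n_ide * 0.3), seed=seed * 7 + 6),
    ]
    return build, ide
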