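"""Terrain and energy predictor derivation from bathymetry.

The predictor suite mirrors what benthic habitat mappers derive with
standard GIS focal tools: Horn 3x3 slope, Zevenbergen–Thorne curvature,
focal standard deviation of slope, a surface-area-ratio rugosity,
bathymetric position indices (BPI) at three annulus scales, summed
wind-wave fetch, and bilinear resampling of coarse ocean-energy grids
onto the analysis grid.

Land cells are expected to carry elevations (negative depth), not
nodata, so shoreline derivatives are defined; :func:`build_stack` masks
the finished layers to the marine footprint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .grids import DepthGrid, PredictorStack

__all__ = [
    "BpiSpec",
    "FetchSpec",
    "DEFAULT_BPI_SPECS",
    "derive_local",
    "bpi",
    "fetch_sum",
    "resample_energy",
    "build_stack",
    "block_mean",
]


@dataclass(frozen=True)
class BpiSpec:
    """Annulus geometry for one bathymetric position index scale."""

    inner: int
    outer: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.inner < self.outer):
            raise ValueError("BPI radii require 0 <= inner < outer")


@dataclass(frozen=True)
class FetchSpec:
    """Ray-casting parameters for summed wind-wave fetch."""

    bearings: int = 32
    cap: float = 50_000.0  # m

    def __post_init__(self) -> None:
        if self.bearings < 8:
            raise ValueError("need at least 8 bearings")
        if self.cap <= 0:
            raise ValueError("fetch cap must be positive")


#: three nested scales, "increasing neighborhood sizes" (cells)
DEFAULT_BPI_SPECS: tuple[BpiSpec, ...] = (
    BpiSpec(0, 5, "fine"),
    BpiSpec(0, 25, "medium"),
    BpiSpec(0, 125, "broad"),
)

_LOCAL_METRICS = ("slope", "curvature", "slope_sd", "rugosity")


def _pad_edge(v: np.ndarray) -> np.ndarray:
    return np.pad(v, 1, mode="edge")


def _fill_nearest(v: np.ndarray) -> np.ndarray:
    """Replace NaNs by the nearest finite value (for window operations)."""
    if not np.isnan(v).any():
        return v
    mask = np.isnan(v)
    idx = ndimage.distance_transform_edt(mask, return_indices=True)[1]
    return v[tuple(idx)]


def _horn_gradients(values: np.ndarray, cell: float) -> tuple[np.ndarray, np.ndarray]:
    z = _pad_edge(_fill_nearest(values))
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, _, f = z[1:-1, :-2], z[1:-1, 1:-1], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dz_dx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cell)
    dz_dy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cell)
    return dz_dx, dz_dy


def _slope_deg(values: np.ndarray, cell: float) -> np.ndarray:
    dz_dx, dz_dy = _horn_gradients(values, cell)
    return np.degrees(np.arctan(np.hypot(dz_dx, dz_dy)))


def _focal_mean_count(valid_values: np.ndarray, valid: np.ndarray, kernel: np.ndarray):
    """Kernel-weighted mean using only the available (valid) cells.

    Direct convolution for small windows (exact), FFT for the large
    BPI annuli (fast).
    """
    if kernel.size <= 49:
        conv = lambda a: ndimage.convolve(a, kernel, mode="constant", cval=0.0)
    else:
        conv = lambda a: fftconvolve(a, kernel, mode="same")
    num = conv(valid_values)
    den = conv(valid.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den, den


def derive_local(bathy: DepthGrid, metric: str) -> np.ndarray:
    """3x3 local terrain derivative of a depth grid.

    * ``slope`` — Horn finite differences, degrees in [0, 90);
    * ``curvature`` — Zevenbergen–Thorne general curvature of the
      elevation surface, signed, in 1/100 m units (positive = convex
      crest);
    * ``slope_sd`` — focal standard deviation of slope in a 3x3
      window (partial windows at edges use the available cells);
    * ``rugosity`` — surface-area / planar-area ratio of the locally
      fitted plane, sec(slope), always >= 1.

    Input nodata (NaN) propagates to the output cell but is excluded
    from neighbours' windows.
    """
    if metric not in _LOCAL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {_LOCAL_METRICS}")
    v = np.asarray(bathy.values, dtype=float)
    if v.shape[0] < 3 or v.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    if np.isnan(v).all():
        raise ValueError("all-nodata grid")
    nan_in = np.isnan(v)
    cell = bathy.cell

    if metric == "slope":
        out = _slope_deg(v, cell)
    elif metric == "rugosity":
        slope_rad = np.radians(_slope_deg(v, cell))
        out = 1.0 / np.cos(slope_rad)
    elif metric == "curvature":
        # on the elevation surface z = -depth; ArcGIS sign convention
        z = _pad_edge(_fill_nearest(-v))
        zc = z[1:-1, 1:-1]
        d2x = (z[1:-1, :-2] + z[1:-1, 2:]) / 2.0 - zc
        d2y = (z[:-2, 1:-1] + z[2:, 1:-1]) / 2.0 - zc
        out = -2.0 * (d2x + d2y) / cell**2 * 100.0
    else:  # slope_sd
        slope = _slope_deg(v, cell)
        valid = ~nan_in
        sv = np.where(valid, slope, 0.0)
        kernel = np.ones((3, 3))
        mean, _ = _focal_mean_count(sv, valid, kernel)
        mean_sq, _ = _focal_mean_count(sv**2, valid, kernel)
        var = np.clip(mean_sq - mean**2, 0.0, None)
        out = np.sqrt(var)

    out[nan_in] = np.nan
    return out


def _annulus_kernel(inner: int, outer: int) -> np.ndarray:
    r = np.arange(-outer, outer + 1)
    dist = np.hypot(*np.meshgrid(r, r, indexing="ij"))
    return ((dist > inner) & (dist <= outer)).astype(float)


def bpi(bathy: DepthGrid, spec: BpiSpec) -> np.ndarray:
    """Bathymetric position index: annulus-mean depth minus cell depth.

    Positive values mark crests (cell shallower than its
    surroundings), negative values depressions. Edge cells use the
    partial annulus that fits on the grid.
    """
    v = np.asarray(bathy.values, dtype=float)
    if min(v.shape) <= spec.outer:
        raise ValueError("BPI outer radius does not fit inside the grid")
    nan_in = np.isnan(v)
    valid = ~nan_in
    kernel = _annulus_kernel(spec.inner, spec.outer)
    mean, _ = _focal_mean_count(np.where(valid, v, 0.0), valid, kernel)
    out = mean - v
    out[nan_in] = np.nan
    return out


def fetch_sum(bathy: DepthGrid, spec: FetchSpec = FetchSpec()) -> np.ndarray:
    """Summed open-water distance to land over equally spaced bearings.

    For each marine cell a ray is marched in cell-sized steps along
    each bearing until it first enters a land cell (depth <= 0); the
    ray contributes that distance, capped at ``spec.cap``. Rays that
    leave the grid are treated as open ocean (cap). Land cells are
    nodata in the output.
    """
    land = bathy.land & ~np.isnan(bathy.values)
    marine = bathy.marine
    if not marine.any():
        raise ValueError("no marine cells")
    nr, nc = bathy.shape
    cell = bathy.cell
    k_max = int(np.ceil(spec.cap / cell))
    total = np.zeros((nr, nc), dtype=float)

    for b in range(spec.bearings):
        theta = 2.0 * np.pi * b / spec.bearings
        de, dn = np.sin(theta), np.cos(theta)  # east, north components
        dist = np.full((nr, nc), spec.cap)
        hit = np.zeros((nr, nc), dtype=bool)
        for k in range(1, k_max + 1):
            dc = int(round(k * de))
            dr = int(round(-k * dn))  # north = decreasing row
            step = min(k * cell, spec.cap)
            # uniform shift: land status of the cell k steps away
            shifted = np.zeros((nr, nc), dtype=bool)
            if abs(dr) >= nr or abs(dc) >= nc:
                continue  # whole shift leaves the grid: open water
            src_r = slice(max(dr, 0), nr + min(dr, 0))
            src_c = slice(max(dc, 0), nc + min(dc, 0))
            dst_r = slice(max(-dr, 0), nr + min(-dr, 0))
            dst_c = slice(max(-dc, 0), nc + min(-dc, 0))
            shifted[dst_r, dst_c] = land[src_r, src_c]
            new = shifted & ~hit
            dist[new] = step
            hit |= new
            if hit[marine].all():
                break
        total += np.minimum(dist, spec.cap)

    total[~marine] = np.nan
    return total


def resample_energy(coarse: DepthGrid, target: DepthGrid) -> np.ndarray:
    """Bilinearly interpolate a coarse energy grid onto the target geometry.

    Exactly reproduces linear fields and the coarse values at
    coinciding cell centers; the result is masked to the target's
    marine cells.
    """
    rows, cols = np.meshgrid(
        np.arange(target.shape[0]), np.arange(target.shape[1]), indexing="ij"
    )
    x, y = target.cell_center(rows, cols)
    # fractional index into the coarse grid (cell centers at i + 0.5)
    ci = (coarse.y0 - y) / coarse.cell - 0.5
    cj = (x - coarse.x0) / coarse.cell - 0.5
    slack = 0.5
    if (
        ci.max() < -slack or cj.max() < -slack
        or ci.min() > coarse.shape[0] - 1 + slack
        or cj.min() > coarse.shape[1] - 1 + slack
    ):
        raise ValueError("coarse and target extents do not overlap")
    out = ndimage.map_coordinates(
        np.asarray(coarse.values, dtype=float), [ci, cj], order=1, mode="nearest"
    )
    out[~target.marine] = np.nan
    return out


def block_mean(bathy: DepthGrid, factor: int) -> DepthGrid:
    """Aggregate to ``factor``-times coarser cells by block averaging.

    Trailing rows/cols that do not fill a block are dropped.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = bathy.shape
    nr2, nc2 = nr // factor, nc // factor
    v = bathy.values[: nr2 * factor, : nc2 * factor]
    coarse = v.reshape(nr2, factor, nc2, factor).mean(axis=(1, 3))
    return DepthGrid(values=coarse, x0=bathy.x0, y0=bathy.y0, cell=bathy.cell * factor)


def build_stack(
    bathy: DepthGrid,
    *,
    tide: DepthGrid,
    circulation: DepthGrid,
    bpi_specs: tuple[BpiSpec, ...] = DEFAULT_BPI_SPECS,
    fetch_spec: FetchSpec = FetchSpec(),
    resolution_class: str = "regional",
) -> PredictorStack:
    """Assemble the full predictor stack on the bathymetry's geometry.

    Layers: depth, slope, curvature, slope_sd, rugosity, one BPI per
    spec, tide, circulation, and — only for the ``regional``
    (fine-resolution) configuration — fetch. All layers are masked to
    the marine footprint.
    """
    if resolution_class not in ("regional", "coastwide"):
        raise ValueError("resolution_class must be 'regional' or 'coastwide'")
    marine = bathy.marine
    stack = PredictorStack(geometry=bathy)

    def masked(arr: np.ndarray) -> np.ndarray:
        out = np.asarray(arr, dtype=float).copy()
        out[~marine] = np.nan
        return out

    stack.add("depth", masked(bathy.values))
    for metric in _LOCAL_METRICS:
        stack.add(metric, masked(derive_local(bathy, metric)))
    for spec in bpi_specs:
        stack.add(f"bpi_{spec.label}", masked(bpi(bathy, spec)))
    stack.add("tide", resample_energy(tide, bathy))
    stack.add("circulation", resample_energy(circulation, bathy))
    if resolution_class == "regional":
        stack.add("fetch", fetch_sum(bathy, fetch_spec))
    return stack
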