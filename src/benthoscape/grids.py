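"""Gridded seafloor containers and GeoTIFF round-trip.

Conventions used throughout the package:

* depth is positive downward (chart-datum convention); land cells carry
  negative depths (elevations) rather than nodata, so shoreline
  derivatives remain defined,
* grids are north-up, square-celled, addressed ``values[row, col]`` with
  row 0 at the northern edge,
* nodata is NaN in memory for continuous grids and 0 for uint8 class
  grids on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import tifffile

__all__ = ["DepthGrid", "PredictorStack", "read_grid", "write_grid"]

# GeoTIFF tag codes understood by GDAL and friends
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass(frozen=True)
class DepthGrid:
    """A regular 2-D grid of depth (m, positive down) with georeferencing.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata. Land cells hold negative
        depths (elevations above chart datum), not nodata.
    x0, y0
        World coordinates (m) of the *outer corner* of cell (0, 0),
        i.e. the north-west corner of the grid.
    cell
        Cell size in metres (square cells).
    """

    values: np.ndarray
    x0: float = 0.0
    y0: float = 0.0
    cell: float = 1.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2:
            raise ValueError(f"grid must be 2-D, got shape {v.shape}")
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        object.__setattr__(self, "values", v)

    # -- geometry ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def geometry(self) -> tuple[float, float, float, tuple[int, int]]:
        return (self.x0, self.y0, self.cell, self.shape)

    def same_geometry(self, other: "DepthGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.cell, other.cell)
        )

    def cell_center(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def index_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing world point(s) (x, y)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cell).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        row, col = self.index_of(x, y)
        nr, nc = self.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)

    # -- masks -------------------------------------------------------
    @property
    def land(self) -> np.ndarray:
        """Boolean mask of cells at or above chart datum (depth <= 0)."""
        with np.errstate(invalid="ignore"):
            return self.values <= 0

    @property
    def marine(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.values > 0

    def with_values(self, values: np.ndarray) -> "DepthGrid":
        return replace(self, values=values)


@dataclass
class PredictorStack:
    """Named, co-registered predictor layers sharing one grid geometry."""

    geometry: DepthGrid
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def add(self, name: str, values: np.ndarray) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name: {name!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != self.geometry.shape:
            raise ValueError(
                f"layer {name!r} shape {values.shape} != stack geometry {self.geometry.shape}"
            )
        self.layers[name] = values

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __iter__(self) -> Iterator[str]:
        return iter(self.layers)

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def nodata_union(self) -> np.ndarray:
        """Cells where any layer is nodata."""
        mask = np.zeros(self.geometry.shape, dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        return mask

    def sample(self, x: np.ndarray, y: np.ndarray) -> Mapping[str, np.ndarray]:
        """Layer values at the cells containing the given points."""
        row, col = self.geometry.index_of(x, y)
        inside = self.geometry.contains(x, y)
        out: dict[str, np.ndarray] = {}
        r = np.clip(row, 0, self.geometry.shape[0] - 1)
        c = np.clip(col, 0, self.geometry.shape[1] - 1)
        for name, arr in self.layers.items():
            vals = arr[r, c].astype(float)
            vals[~inside] = np.nan
            out[name] = vals
        return out


# -- GeoTIFF I/O -----------------------------------------------------

def write_grid(grid: DepthGrid, path, *, as_classes: bool = False) -> None:
    """Write a grid as a single-band GeoTIFF.

    Continuous grids go out as float32 with NaN nodata; with
    ``as_classes=True`` values are written uint8 with 0 = nodata
    (class codes 1..K).
    """
    if as_classes:
        data = np.nan_to_num(grid.values, nan=0.0).astype(np.uint8)
        nodata = "0"
    else:
        data = grid.values.astype(np.float32)
        nodata = "nan"
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell, grid.cell, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, grid.y0, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, nodata),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_grid(path) -> DepthGrid:
    """Read a single-band GeoTIFF written by :func:`write_grid`."""
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
            raise ValueError(f"{path}: missing georeferencing tags")
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        nodata = tags[_TAG_GDAL_NODATA].value if _TAG_GDAL_NODATA in tags else "nan"
    values = np.asarray(data, dtype=float)
    if nodata not in ("nan", "NaN"):
        values[values == float(nodata)] = np.nan
    return DepthGrid(values=values, x0=float(tie[3]), y0=float(tie[4]), cell=float(scale[0]))
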