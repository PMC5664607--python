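"""Planar grid data model and the geometric/zonal primitives.

All rasters in one analysis live on a single common grid: square cells of
``cell_size_m`` metres in a planar projected coordinate system, row-major
arrays with 0-based indices, origin at the outer corner of cell (0, 0)
(upper-left). Reprojection and resampling are deliberately out of scope —
inputs must be pre-aligned.

Conventions:

* Buffer membership is decided by cell-*center* Euclidean distance, the
  standard raster convention; at 30 m cells against km-scale buffers the
  error relative to any-overlap membership is sub-cell.
* nodata cells are treated as ``False`` in masks and as failing any
  suitability condition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy import ndimage

from .errors import ArgumentError, AlignmentError, EmptyZoneError, InvalidRasterError

Kind = Literal["continuous", "categorical", "boolean"]
Connectivity = Literal["edge", "edge+corner"]

#: cell-unit slack on the inclusive dilation radius; absorbs float sqrt
#: representation at exact-tie radii (a cell at exactly ``distance_m``)
_RADIUS_EPS = 1e-9


@dataclass
class GridRaster:
    """A single-band raster on the common analysis grid.

    Parameters
    ----------
    values
        2-D array; numbers for continuous layers, integer codes for
        categorical layers, bools for boolean layers.
    cell_size_m
        Side length of the square cells, metres. Must be positive.
    origin_xy
        Planar (x, y) coordinates in metres of the outer corner of cell
        (0, 0), i.e. the upper-left corner of the grid.
    nodata
        Sentinel marking invalid cells, or ``None`` when every cell is valid.
    kind
        One of ``continuous``, ``categorical``, ``boolean``.
    """

    values: np.ndarray
    cell_size_m: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata: float | int | None = None
    kind: Kind = "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise InvalidRasterError(f"raster values must be 2-D, got {self.values.ndim}-D")
        if not (self.cell_size_m > 0):
            raise InvalidRasterError(f"cell_size_m must be positive, got {self.cell_size_m}")
        if self.kind == "boolean" and self.values.dtype != bool:
            raise InvalidRasterError("boolean raster requires a bool-dtype array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def grid_key(self) -> tuple:
        """Identity of the underlying grid, for alignment checks."""
        return (self.shape, float(self.cell_size_m), tuple(map(float, self.origin_xy)))

    def data_mask(self) -> np.ndarray:
        """Boolean array of cells carrying valid data."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.values)
        return self.values != self.nodata

    def like(self, values: np.ndarray, *, kind: Kind | None = None,
             nodata: float | int | None = None) -> "GridRaster":
        """New raster on the same grid with different values."""
        return GridRaster(values, self.cell_size_m, self.origin_xy,
                          nodata=nodata, kind=kind or self.kind)


class Mask(GridRaster):
    """A boolean raster; nodata cells are folded into ``False`` on creation."""

    def __init__(self, values: np.ndarray, cell_size_m: float,
                 origin_xy: tuple[float, float] = (0.0, 0.0)):
        arr = np.asarray(values)
        if arr.dtype != bool:
            if not np.isin(arr[~np.isnan(arr.astype(float))], (0, 1)).all():
                raise InvalidRasterError("mask values must be boolean or {0,1}")
            arr = np.nan_to_num(arr.astype(float), nan=0.0).astype(bool)
        super().__init__(arr, cell_size_m, origin_xy, nodata=None, kind="boolean")

    @classmethod
    def from_raster(cls, raster: GridRaster) -> "Mask":
        vals = raster.values.astype(bool) & raster.data_mask()
        return cls(vals, raster.cell_size_m, raster.origin_xy)

    def count(self) -> int:
        return int(self.values.sum())

    def __and__(self, other: "Mask") -> "Mask":
        require_aligned(self, other)
        return Mask(self.values & other.values, self.cell_size_m, self.origin_xy)

    def __or__(self, other: "Mask") -> "Mask":
        require_aligned(self, other)
        return Mask(self.values | other.values, self.cell_size_m, self.origin_xy)


def require_aligned(*rasters: GridRaster) -> None:
    """Raise :class:`AlignmentError` unless all rasters share one grid."""
    keys = {r.grid_key() for r in rasters}
    if len(keys) > 1:
        raise AlignmentError(f"rasters are not grid-aligned: {sorted(map(str, keys))}")


@dataclass
class ClimateStack:
    """Twelve monthly layers each of precipitation (mm), minimum and maximum
    surface temperature (°C), all on the common grid."""

    precip: list[GridRaster]
    tmin: list[GridRaster]
    tmax: list[GridRaster]

    def __post_init__(self) -> None:
        for name, layers in (("precip", self.precip), ("tmin", self.tmin), ("tmax", self.tmax)):
            if len(layers) != 12:
                raise InvalidRasterError(f"{name} must have exactly 12 monthly layers")
        require_aligned(*self.precip, *self.tmin, *self.tmax)
        for lo, hi in zip(self.tmin, self.tmax):
            valid = lo.data_mask() & hi.data_mask()
            if np.any(lo.values[valid] > hi.values[valid]):
                raise InvalidRasterError("tmin exceeds tmax on some valid cells")

    @property
    def grid(self) -> GridRaster:
        return self.precip[0]


@dataclass
class SoilLayers:
    """Soil depth (cm, continuous) and texture class (categorical codes)."""

    depth: GridRaster
    texture: GridRaster

    def __post_init__(self) -> None:
        require_aligned(self.depth, self.texture)
        valid = self.depth.data_mask()
        if np.any(self.depth.values[valid] < 0):
            raise InvalidRasterError("soil depth must be >= 0 outside nodata")


@dataclass
class LandUseLayer:
    """Categorical land-use raster plus its code table.

    The code table maps semantic names to integer codes and must contain at
    least ``fallow_cropland``; per-crop cultivation classes are named by
    crop id.
    """

    raster: GridRaster
    codes: Mapping[str, int]

    def __post_init__(self) -> None:
        if "fallow_cropland" not in self.codes:
            raise InvalidRasterError("land-use code table must define 'fallow_cropland'")
        present = np.unique(self.raster.values[self.raster.data_mask()])
        known = set(int(v) for v in self.codes.values())
        unknown = [int(c) for c in present if int(c) not in known]
        if unknown:
            raise InvalidRasterError(f"land-use codes not in code table: {unknown}")

    def class_mask(self, name: str) -> Mask:
        code = self.codes[name]
        vals = (self.raster.values == code) & self.raster.data_mask()
        return Mask(vals, self.raster.cell_size_m, self.raster.origin_xy)


# ---------------------------------------------------------------------------
# operations


def cell_area_ha(raster: GridRaster) -> float:
    """Area of one grid cell in hectares (``cell_size_m**2 / 10_000``)."""
    if not (raster.cell_size_m > 0):
        raise InvalidRasterError("cell size must be positive")
    return raster.cell_size_m ** 2 / 10_000.0


def mask_area_ha(mask: Mask) -> float:
    """Exact area covered by true cells, hectares (count x cell area)."""
    return mask.count() * cell_area_ha(mask)


def dilate_mask(mask: Mask, distance_m: float) -> Mask:
    """Euclidean dilation: true wherever a cell center lies within
    ``distance_m`` of the center of some input true cell.

    Output always contains the input; ``distance_m = 0`` is the identity.
    """
    if distance_m < 0:
        raise ArgumentError(f"dilation distance must be >= 0, got {distance_m}")
    if distance_m == 0 or not mask.values.any():
        return Mask(mask.values.copy(), mask.cell_size_m, mask.origin_xy)
    # exact Euclidean distance (in cell units) from every cell to the
    # nearest true cell; inclusive threshold with a tiny slack so cells at
    # exactly distance_m survive float sqrt rounding
    dist = ndimage.distance_transform_edt(~mask.values)
    radius_cells = distance_m / mask.cell_size_m
    out = dist <= radius_cells + _RADIUS_EPS
    return Mask(out, mask.cell_size_m, mask.origin_xy)


_STRUCTURES = {
    "edge": ndimage.generate_binary_structure(2, 1),
    "edge+corner": ndimage.generate_binary_structure(2, 2),
}


def connected_components(mask: Mask, connectivity: Connectivity = "edge"
                         ) -> tuple[np.ndarray, int]:
    """Label connected components of true cells.

    Returns ``(labels, n)`` where ``labels`` is an int array with 0 on false
    cells and 1..n on true cells; two true cells share a label iff they are
    connected under ``connectivity`` (``edge`` = rook, ``edge+corner`` =
    queen).
    """
    if connectivity not in _STRUCTURES:
        raise ArgumentError(f"unknown connectivity {connectivity!r}")
    labels, n = ndimage.label(mask.values, structure=_STRUCTURES[connectivity])
    return labels, int(n)


def zonal_min_max(raster: GridRaster, zone: Mask) -> tuple[float, float]:
    """(min, max) of a continuous raster over in-zone, valid-data cells."""
    require_aligned(raster, zone)
    sel = zone.values & raster.data_mask()
    if not sel.any():
        raise EmptyZoneError("zone contains no valid-data cells")
    vals = raster.values[sel]
    return float(vals.min()), float(vals.max())
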