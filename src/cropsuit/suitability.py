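"""Per-crop growing requirements and the boolean overlay.

A cell is suitable for a crop iff *all* of the crop's active conditions
hold there: membership in the analysis region, fallow-cropland land use,
monthly precipitation and min/max temperature inside per-month bounds,
minimum soil depth, and allowed soil texture class. Only the conditions
relevant to a crop participate (e.g. an indoor crop may use land use
alone). The model is strictly boolean — there is no continuous scoring.

Where published growing-condition bounds are unavailable or coarser than
the raster data, bounds are derived from observed climate extrema over a
reference zone: the whole production center, or the clusters covering at
least 95% of the crop's cultivated cells when crop-specific land-use data
support it. Bound comparisons are inclusive so that derived-bound source
cells always remain suitable.

Every overlay records a filter cascade — the surviving cell count after
each condition — so the binding constraint is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence
import warnings

import numpy as np

from .errors import ArgumentError, ConfigurationError, EmptyCropError
from .raster_core import (
    ClimateStack,
    Connectivity,
    GridRaster,
    LandUseLayer,
    Mask,
    SoilLayers,
    connected_components,
    require_aligned,
    zonal_min_max,
)

Condition = Literal["precip", "tmin", "tmax", "soil_depth", "texture", "fallow"]
CLIMATE_VARS = ("precip", "tmin", "tmax")

#: USDA soil-texture-triangle classes; site-specific codes map onto these
USDA_TEXTURE_CLASSES = {
    1: "sand", 2: "loamy sand", 3: "sandy loam", 4: "loam", 5: "silt loam",
    6: "silt", 7: "sandy clay loam", 8: "clay loam", 9: "silty clay loam",
    10: "sandy clay", 11: "silty clay", 12: "clay",
}

MonthlyBounds = tuple[tuple[float, float], ...]  # 12 (low, high) pairs


def _check_bounds(name: str, bounds: MonthlyBounds | None) -> None:
    if bounds is None:
        return
    if len(bounds) != 12:
        raise ConfigurationError(f"{name} needs 12 monthly (low, high) pairs")
    for m, (lo, hi) in enumerate(bounds, start=1):
        if lo > hi:
            raise ConfigurationError(f"{name} month {m}: low {lo} > high {hi}")


@dataclass
class CropRequirement:
    """Growing conditions for one crop, with an explicit active-condition list.

    Bounds for inactive conditions are tolerated with a warning (they are
    ignored); an active condition with no bounds is an error, caught at
    overlay time when derived bounds are also absent.
    """

    crop_id: str
    active_conditions: tuple[Condition, ...]
    precip_bounds: MonthlyBounds | None = None
    tmin_bounds: MonthlyBounds | None = None
    tmax_bounds: MonthlyBounds | None = None
    soil_depth_min_cm: float | None = None
    allowed_textures: frozenset[int] | None = None
    require_fallow: bool = True

    def __post_init__(self):
        if not self.active_conditions:
            raise ConfigurationError(f"crop {self.crop_id}: at least one condition must be active")
        unknown = set(self.active_conditions) - {"precip", "tmin", "tmax",
                                                 "soil_depth", "texture", "fallow"}
        if unknown:
            raise ConfigurationError(f"crop {self.crop_id}: unknown conditions {sorted(unknown)}")
        for name, b in (("precip_bounds", self.precip_bounds),
                        ("tmin_bounds", self.tmin_bounds),
                        ("tmax_bounds", self.tmax_bounds)):
            _check_bounds(name, b)
        supplied = {"precip": self.precip_bounds is not None,
                    "tmin": self.tmin_bounds is not None,
                    "tmax": self.tmax_bounds is not None,
                    "soil_depth": self.soil_depth_min_cm is not None,
                    "texture": self.allowed_textures is not None}
        for cond, given in supplied.items():
            if given and cond not in self.active_conditions:
                warnings.warn(
                    f"crop {self.crop_id}: bounds supplied for inactive condition "
                    f"{cond!r}; they will be ignored", stacklevel=2)

    def bounds_for(self, var: str) -> MonthlyBounds | None:
        return {"precip": self.precip_bounds, "tmin": self.tmin_bounds,
                "tmax": self.tmax_bounds}[var]


@dataclass
class DerivedBounds:
    """Per-variable monthly (low, high) ranges observed over a reference zone."""

    bounds: Mapping[str, MonthlyBounds]  # var -> 12 pairs
    provenance: Literal["whole_center", "crop_clusters"]

    def __post_init__(self):
        for var, b in self.bounds.items():
            _check_bounds(f"derived {var}", b)


def derive_bounds(stack: ClimateStack, zone: Mask,
                  provenance: Literal["whole_center", "crop_clusters"] = "whole_center",
                  ) -> DerivedBounds:
    """Monthly (min, max) of each climate variable over ``zone``.

    By construction every in-zone cell satisfies its own derived bounds
    (inclusive comparison downstream).
    """
    out = {}
    for var in CLIMATE_VARS:
        layers: Sequence[GridRaster] = getattr(stack, var)
        out[var] = tuple(zonal_min_max(layer, zone) for layer in layers)
    return DerivedBounds(bounds=out, provenance=provenance)


def crop_clusters(landuse: LandUseLayer, crop_code: str, coverage: float = 0.95,
                  connectivity: Connectivity = "edge") -> Mask:
    """Smallest set of largest cultivation clusters covering >= ``coverage``
    of a crop's cells.

    Components of the crop's cultivation cells are sorted by size
    (descending, ties by smaller label); the prefix whose cumulative cell
    count first reaches ``coverage`` x total is returned as one mask.
    """
    if not (0 < coverage <= 1):
        raise ArgumentError(f"coverage must be in (0, 1], got {coverage}")
    if crop_code not in landuse.codes:
        raise ArgumentError(f"crop code {crop_code!r} not in land-use code table")
    cells = landuse.class_mask(crop_code)
    total = cells.count()
    if total == 0:
        raise EmptyCropError(f"no cells of crop {crop_code!r} in land-use layer")
    labels, n = connected_components(cells, connectivity)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]  # size of label i at i-1
    order = np.lexsort((np.arange(1, n + 1), -sizes))  # descending size, then label
    cum = np.cumsum(sizes[order])
    k = int(np.searchsorted(cum, coverage * total - 1e-9) + 1)
    keep = set((order[:k] + 1).tolist())
    vals = np.isin(labels, list(keep))
    return Mask(vals, cells.cell_size_m, cells.origin_xy)


def _within_monthly(layers: Sequence[GridRaster], bounds: MonthlyBounds) -> np.ndarray:
    """Cells whose value is inside the month's inclusive bounds for all 12
    months, with valid data every month."""
    ok = np.ones(layers[0].shape, dtype=bool)
    for layer, (lo, hi) in zip(layers, bounds):
        ok &= layer.data_mask() & (layer.values >= lo) & (layer.values <= hi)
    return ok


def evaluate_suitability(
    climate: ClimateStack | None,
    soil: SoilLayers | None,
    landuse: LandUseLayer | None,
    req: CropRequirement,
    region: Mask,
    derived: DerivedBounds | None = None,
    cascade: dict[str, int] | None = None,
) -> Mask:
    """Boolean overlay: suitable iff every active condition holds.

    For each active climate variable, published bounds (on ``req``) take
    precedence; ``derived`` bounds fill in where the requirement supplies
    none. nodata in any active layer makes a cell unsuitable. Pass a dict
    as ``cascade`` to capture surviving cell counts per condition.
    """
    layers_for_alignment = [region]
    if climate is not None:
        layers_for_alignment.append(climate.grid)
    if soil is not None:
        layers_for_alignment.append(soil.depth)
    if landuse is not None:
        layers_for_alignment.append(landuse.raster)
    require_aligned(*layers_for_alignment)

    ok = region.values.copy()
    log = cascade if cascade is not None else {}
    log["region"] = int(ok.sum())

    if "fallow" in req.active_conditions and req.require_fallow:
        if landuse is None:
            raise ConfigurationError(f"crop {req.crop_id}: fallow active but no land-use layer")
        ok &= landuse.class_mask("fallow_cropland").values
        log["fallow"] = int(ok.sum())

    for var in CLIMATE_VARS:
        if var not in req.active_conditions:
            continue
        bounds = req.bounds_for(var)
        if bounds is None and derived is not None:
            bounds = derived.bounds.get(var)
        if bounds is None:
            raise ConfigurationError(
                f"crop {req.crop_id}: {var} active but neither published nor derived bounds given")
        if climate is None:
            raise ConfigurationError(f"crop {req.crop_id}: {var} active but no climate stack")
        ok &= _within_monthly(getattr(climate, var), bounds)
        log[var] = int(ok.sum())

    if "soil_depth" in req.active_conditions:
        if soil is None or req.soil_depth_min_cm is None:
            raise ConfigurationError(f"crop {req.crop_id}: soil_depth active but unparameterised")
        ok &= soil.depth.data_mask() & (soil.depth.values >= req.soil_depth_min_cm)
        log["soil_depth"] = int(ok.sum())

    if "texture" in req.active_conditions:
        if soil is None or req.allowed_textures is None:
            raise ConfigurationError(f"crop {req.crop_id}: texture active but unparameterised")
        ok &= soil.texture.data_mask() & np.isin(soil.texture.values,
                                                 list(req.allowed_textures))
        log["texture"] = int(ok.sum())

    return Mask(ok, region.cell_size_m, region.origin_xy)
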