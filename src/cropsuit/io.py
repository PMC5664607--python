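"""Readers and writers binding the pipeline stages to files.

Rasters travel as ESRI ASCII grids (``.asc``) — a plain-text header
(ncols/nrows/xllcorner/yllcorner/cellsize/nodata_value) followed by
row-major values, upper-left first. Masks are stored with values {0, 1}
and nodata 255. Tables are CSV; configuration (crop requirements, run
parameters) is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .availability import LossChain, YieldRecord
from .errors import ConfigurationError, InvalidRasterError
from .production_centers import CountyRecord
from .raster_core import GridRaster, Kind, Mask
from .suitability import CropRequirement

MASK_NODATA = 255

# --------------------------------------------------------------------------
# ESRI ASCII grid


def write_ascii_grid(raster: GridRaster, path: str | Path) -> None:
    """Write a raster as an ESRI ASCII grid.

    ``origin_xy`` is the upper-left outer corner; the format stores the
    lower-left corner, so ``yllcorner = origin_y - nrows * cellsize``.
    """
    path = Path(path)
    nrows, ncols = raster.shape
    x0, y0 = raster.origin_xy
    nodata = raster.nodata if raster.nodata is not None else -9999
    vals = raster.values
    if raster.kind == "boolean":
        vals = vals.astype(np.uint8)
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {y0 - nrows * raster.cell_size_m}\n"
        f"cellsize {raster.cell_size_m}\n"
        f"nodata_value {nodata}\n"
    )
    fmt = "%d" if np.issubdtype(np.asarray(vals).dtype, np.integer) else "%.10g"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt=fmt)


def read_ascii_grid(path: str | Path, kind: Kind = "continuous",
                    nodata_is_none_if_unused: bool = True) -> GridRaster:
    """Read an ESRI ASCII grid back into a :class:`GridRaster`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.strip().partition(" ")
            key = key.lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise InvalidRasterError(f"{path}: missing {req} in ASCII grid header")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (nrows, ncols):
        raise InvalidRasterError(
            f"{path}: data shape {values.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    origin = (header.get("xllcorner", 0.0), header.get("yllcorner", 0.0) + nrows * cell)
    nodata = header.get("nodata_value")
    if kind == "categorical":
        values = values.astype(np.int64)
        nodata = int(nodata) if nodata is not None else None
    if nodata is not None and nodata_is_none_if_unused:
        unused = (not np.isin(values, nodata).any()) if not np.isnan(nodata) \
            else not np.isnan(values).any()
        if unused:
            nodata = None
    if kind == "boolean":
        data = values != (nodata if nodata is not None else MASK_NODATA)
        return Mask((values == 1) & data, cell, origin)
    return GridRaster(values, cell, origin, nodata=nodata, kind=kind)


def write_mask(mask: Mask, path: str | Path) -> None:
    """Store a mask with values {0, 1} and nodata 255."""
    as_int = mask.like(mask.values.astype(np.uint8), kind="categorical",
                       nodata=MASK_NODATA)
    write_ascii_grid(as_int, path)


def read_mask(path: str | Path) -> Mask:
    return read_ascii_grid(path, kind="boolean",
                           nodata_is_none_if_unused=False)  # type: ignore[return-value]


# --------------------------------------------------------------------------
# tables


def read_yields_csv(path: str | Path) -> dict[tuple[str, str], YieldRecord]:
    """CSV columns: crop_id, state, kg_per_ha -> {(crop, state): record}."""
    df = pd.read_csv(path)
    return {(r.crop_id, r.state): YieldRecord(r.crop_id, r.state, float(r.kg_per_ha))
            for r in df.itertuples()}


def read_losses_csv(path: str | Path) -> dict[str, LossChain]:
    """CSV columns: crop_id, farm_loss, retail_loss, consumer_loss, cups_per_kg."""
    df = pd.read_csv(path)
    return {r.crop_id: LossChain(r.crop_id, float(r.farm_loss), float(r.retail_loss),
                                 float(r.consumer_loss), float(r.cups_per_kg))
            for r in df.itertuples()}


def read_acreage_csv(path: str | Path) -> pd.DataFrame:
    """Long-format county acreage: county_id, state, year, crop_id, acreage_ha."""
    df = pd.read_csv(path)
    needed = {"county_id", "state", "year", "crop_id", "acreage_ha"}
    if not needed.issubset(df.columns):
        raise ConfigurationError(f"{path}: acreage CSV needs columns {sorted(needed)}")
    return df


def counties_from_tables(acreage: pd.DataFrame, county_labels: GridRaster,
                         label_map: Mapping[str, int], crop_id: str,
                         ) -> list[CountyRecord]:
    """Assemble :class:`CountyRecord` objects for one crop from a long
    acreage table and a county-label raster."""
    sub = acreage[acreage["crop_id"] == crop_id]
    counties = []
    for county_id, grp in sub.groupby("county_id"):
        code = label_map[county_id]
        mask = Mask(county_labels.values == code, county_labels.cell_size_m,
                    county_labels.origin_xy)
        counties.append(CountyRecord(
            county_id=str(county_id), state=str(grp["state"].iloc[0]), mask=mask,
            acreage_by_year={int(r.year): float(r.acreage_ha) for r in grp.itertuples()}))
    return counties


# --------------------------------------------------------------------------
# crop-requirement YAML


def _monthly(block, name):
    if block is None:
        return None
    if len(block) != 12:
        raise ConfigurationError(f"{name}: expected 12 monthly [low, high] pairs")
    return tuple((float(lo), float(hi)) for lo, hi in block)


def read_requirements_yaml(path: str | Path) -> dict[str, CropRequirement]:
    """Per-crop requirement blocks.

    Schema per crop: ``active`` (list of condition names), optional
    ``precip``/``tmin``/``tmax`` (12 x [low, high]), ``soil_depth_min_cm``,
    ``allowed_textures`` (list of class codes), ``require_fallow``.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    out = {}
    for crop_id, block in doc.items():
        out[crop_id] = CropRequirement(
            crop_id=crop_id,
            active_conditions=tuple(block["active"]),
            precip_bounds=_monthly(block.get("precip"), f"{crop_id}.precip"),
            tmin_bounds=_monthly(block.get("tmin"), f"{crop_id}.tmin"),
            tmax_bounds=_monthly(block.get("tmax"), f"{crop_id}.tmax"),
            soil_depth_min_cm=block.get("soil_depth_min_cm"),
            allowed_textures=(frozenset(block["allowed_textures"])
                              if "allowed_textures" in block else None),
            require_fallow=bool(block.get("require_fallow", True)),
        )
    return out


def write_requirements_yaml(reqs: Mapping[str, CropRequirement], path: str | Path) -> None:
    doc = {}
    for crop_id, r in reqs.items():
        block: dict = {"active": list(r.active_conditions),
                       "require_fallow": r.require_fallow}
        for name, b in (("precip", r.precip_bounds), ("tmin", r.tmin_bounds),
                        ("tmax", r.tmax_bounds)):
            if b is not None:
                block[name] = [[float(lo), float(hi)] for lo, hi in b]
        if r.soil_depth_min_cm is not None:
            block["soil_depth_min_cm"] = float(r.soil_depth_min_cm)
        if r.allowed_textures is not None:
            block["allowed_textures"] = sorted(int(t) for t in r.allowed_textures)
        doc[crop_id] = block
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON (sorted keys, fixed separators) for run manifests."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
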