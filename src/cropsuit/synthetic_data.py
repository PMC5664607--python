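"""Synthetic, grid-aligned input bundles with analytically known truth.

The real analysis consumes national climate normals, a gridded soil survey,
a cropland data layer and census county acreage — none redistributable at
desk scale. This module emulates their *structure*: planar projected
rasters on one common grid, spatially smooth monthly climate fields,
categorical soil and land-use fields, and county acreage tables with
designated dominant counties. It makes no attempt to match the real data
in distribution; its purpose is exactness, not realism.

:func:`gen_truth_case` constructs a complete bundle whose correct pipeline
output is known in closed form: a target rectangle of fallow, fully
suitable cells inside the production-center county, additional rectangles
placed inside each buffer annulus at exact cell-center distances, and
distractor fallow patches each failing exactly one growing condition.
Expected areas are cell counts x cell area; expected cup-equivalents
follow the availability chain arithmetic.

All randomness flows from a single integer seed fanned out per layer, so
identical seeds give bit-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .availability import LossChain, YieldRecord
from .errors import GenerationError
from .production_centers import CountyRecord
from .raster_core import ClimateStack, GridRaster, LandUseLayer, Mask, SoilLayers
from .suitability import CropRequirement

LANDUSE_CODES = {"other": 0, "fallow_cropland": 1}


@dataclass(frozen=True)
class GridSpec:
    """Shape and geometry of the common synthetic grid."""

    shape: tuple[int, int] = (300, 300)
    cell_size_m: float = 30.0
    origin_xy: tuple[float, float] = (0.0, 0.0)


@dataclass(frozen=True)
class ClimateSpec:
    """Deterministic monthly ramps plus seeded noise.

    Precipitation ramps along rows from ``precip_lo[m]`` to ``precip_hi[m]``;
    minimum temperature ramps along columns from ``tmin_lo[m]`` to
    ``tmin_hi[m]``; maximum temperature is the minimum plus a positive
    spread. With ``noise_amplitude=0`` the fields are pure ramps whose
    extrema are the spec endpoints. Noise is uniform in +/- amplitude and
    never violates tmin <= tmax (the spread exceeds twice the amplitude).
    """

    precip_lo: tuple[float, ...] = tuple(40.0 + 30.0 * np.sin(2 * np.pi * m / 12) for m in range(12))
    precip_range: float = 60.0
    tmin_lo: tuple[float, ...] = tuple(-5.0 + 15.0 * np.sin(2 * np.pi * (m - 3) / 12) for m in range(12))
    tmin_range: float = 10.0
    tmax_spread: float = 8.0
    noise_amplitude: float = 1.0

    def __post_init__(self):
        if self.noise_amplitude < 0:
            raise GenerationError("noise amplitude must be >= 0")
        if self.tmax_spread <= 2 * self.noise_amplitude:
            raise GenerationError("tmax_spread must exceed twice the noise amplitude")


def _ramp(shape: tuple[int, int], lo: float, hi: float, axis: int) -> np.ndarray:
    n = shape[axis]
    line = np.linspace(lo, hi, n)
    return np.broadcast_to(line[:, None] if axis == 0 else line[None, :], shape).copy()


def gen_climate(grid: GridSpec, seed: int, spec: ClimateSpec | None = None) -> ClimateStack:
    """Twelve-month precipitation and min/max temperature stacks."""
    spec = spec or ClimateSpec()
    rng = np.random.default_rng(seed)
    precip, tmin, tmax = [], [], []
    for m in range(12):
        a = spec.noise_amplitude
        p = _ramp(grid.shape, spec.precip_lo[m], spec.precip_lo[m] + spec.precip_range, axis=0)
        t = _ramp(grid.shape, spec.tmin_lo[m], spec.tmin_lo[m] + spec.tmin_range, axis=1)
        if a > 0:
            p = p + rng.uniform(-a, a, grid.shape)
            t = t + rng.uniform(-a, a, grid.shape)
        hi = t + spec.tmax_spread + (rng.uniform(-a, a, grid.shape) if a > 0 else 0.0)
        for layers, vals in ((precip, np.maximum(p, 0.0)), (tmin, t), (tmax, hi)):
            layers.append(GridRaster(vals, grid.cell_size_m, grid.origin_xy))
    return ClimateStack(precip=precip, tmin=tmin, tmax=tmax)


def gen_counties(grid: GridSpec, tiles: tuple[int, int], crop_id: str,
                 shares: Mapping[int, float], seed: int,
                 years: Sequence[int] = tuple(range(2002, 2013)),
                 national_total_ha: float = 100_000.0,
                 states: Mapping[int, str] | None = None,
                 ) -> tuple[list[CountyRecord], pd.DataFrame]:
    """Rectangular county tiling plus an acreage table realising ``shares``.

    ``shares`` maps flat tile index -> fraction of mean national acreage;
    unassigned counties split the remainder evenly. Acreage varies by year
    (seeded, +/-20% around each county's mean) while holding every county's
    *mean* share exact, so threshold screening sees the designed shares.
    """
    if sum(shares.values()) > 1 + 1e-12:
        raise GenerationError("designated shares exceed 1")
    nr, nc = tiles
    rows, cols = grid.shape
    if rows % nr or cols % nc:
        raise GenerationError(f"grid {grid.shape} not divisible into {tiles} tiles")
    th, tw = rows // nr, cols // nc
    n = nr * nc
    rest = (1.0 - sum(shares.values())) / max(n - len(shares), 1)
    rng = np.random.default_rng(seed)
    counties, records = [], []
    for idx in range(n):
        r, c = divmod(idx, nc)
        mask_vals = np.zeros(grid.shape, dtype=bool)
        mask_vals[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = True
        share = shares.get(idx, rest)
        mean_acreage = share * national_total_ha
        # year-to-year variation that averages out exactly
        wiggle = rng.uniform(-0.2, 0.2, len(years))
        wiggle -= wiggle.mean()
        acreage = {int(y): mean_acreage * (1 + w) for y, w in zip(years, wiggle)}
        county = CountyRecord(
            county_id=f"county_{idx:03d}",
            state=(states or {}).get(idx, "SY"),
            mask=Mask(mask_vals, grid.cell_size_m, grid.origin_xy),
            acreage_by_year=acreage,
        )
        counties.append(county)
        for y, a in acreage.items():
            records.append({"county_id": county.county_id, "state": county.state,
                            "year": y, "crop_id": crop_id, "acreage_ha": a})
    return counties, pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class TruthDesign:
    """Placement plan for a ground-truth case.

    The default grid uses 100 m cells on a 500x500 grid (50 km x 50 km) so
    the full 0-20 km buffer ladder fits; rectangle offsets are in whole
    cells measured horizontally from the production-center county's right
    edge, making every buffer-membership decision exact (distance =
    offset x cell size). Ring k's rectangle sits strictly inside the
    (buffer k-1, buffer k] annulus.
    """

    grid: GridSpec = GridSpec(shape=(500, 500), cell_size_m=100.0)
    crop_id: str = "crop_a"
    county_tiles: tuple[int, int] = (5, 5)
    center_tile: int = 12                 # middle tile of a 5x5 tiling
    center_share: float = 0.55
    buffers_km: tuple[float, ...] = (0, 5, 10, 15, 20)
    # target rectangle inside the center county: (row0, col0, height, width)
    target_rect: tuple[int, int, int, int] = (220, 220, 20, 30)
    # per-ring (start_offset_cells, width, row0, height); cell counts are
    # width x height = 100, 200, 300, 400 by default
    ring_rects: tuple[tuple[int, int, int, int], ...] = (
        (10, 10, 240, 10), (60, 10, 240, 20), (110, 10, 240, 30), (160, 10, 240, 40))
    yield_kg_per_ha: float = 10_000.0
    farm_loss: float = 0.1
    retail_loss: float = 0.2
    consumer_loss: float = 0.3
    cups_per_kg: float = 1.0
    population: float = 1_000_000.0
    soil_depth_cm: float = 150.0
    soil_depth_min_cm: float = 50.0
    texture_code: int = 4
    allowed_textures: frozenset = frozenset({4, 5})


@dataclass
class TruthCase:
    """A complete input bundle plus its closed-form expected results."""

    seed: int
    design: TruthDesign
    climate: ClimateStack
    soil: SoilLayers
    landuse: LandUseLayer
    counties: list[CountyRecord]
    acreage: pd.DataFrame
    requirement: CropRequirement
    yields: YieldRecord
    losses: LossChain
    population: float
    expected_masks: dict[float, Mask]       # buffer_km -> suitable mask
    expected_area_ha: dict[float, float]
    expected_cups: dict[float, float]


def gen_truth_case(design: TruthDesign | None = None, seed: int = 0) -> TruthCase:
    """Build a bundle whose pipeline output is known in closed form."""
    d = design or TruthDesign()
    grid = d.grid
    rows, cols = grid.shape
    nr, nc = d.county_tiles
    th, tw = rows // nr, cols // nc
    cr, cc = divmod(d.center_tile, nc)
    county_r0, county_c0 = cr * th, cc * tw
    county_r1, county_c1 = county_r0 + th, county_c0 + tw  # exclusive

    # --- land use: fallow exactly at target + rings + distractors ---------
    fallow = np.zeros(grid.shape, dtype=bool)
    r0, c0, h, w = d.target_rect
    if not (county_r0 <= r0 and r0 + h <= county_r1
            and county_c0 <= c0 and c0 + w <= county_c1):
        raise GenerationError("target rectangle must lie inside the center county tile")
    fallow[r0:r0 + h, c0:c0 + w] = True
    target_cells = h * w

    cell_km = grid.cell_size_m / 1000.0
    ring_cells = []
    ring_masks = []
    for k, (off, rw, rr0, rh) in enumerate(d.ring_rects):
        lo_km, hi_km = d.buffers_km[k], d.buffers_km[k + 1]
        if not (off * cell_km > lo_km and (off + rw - 1) * cell_km <= hi_km):
            raise GenerationError(f"ring {k + 1} offsets not inside its buffer annulus")
        if not (county_r0 <= rr0 and rr0 + rh <= county_r1):
            raise GenerationError(f"ring {k + 1} rows must stay within the county row span")
        rc0 = county_c1 - 1 + off
        if rc0 + rw > cols:
            raise GenerationError(f"ring {k + 1} extends past the grid edge")
        ring = np.zeros(grid.shape, dtype=bool)
        ring[rr0:rr0 + rh, rc0:rc0 + rw] = True
        fallow |= ring
        ring_masks.append(ring)
        ring_cells.append(rh * rw)

    # distractor fallow patches, each failing exactly one condition; placed
    # inside the center county so they sit in every scenario region
    bad_climate = np.zeros(grid.shape, dtype=bool)
    bad_climate[county_r0 + 2:county_r0 + 6, county_c0 + 2:county_c0 + 6] = True
    bad_depth = np.zeros(grid.shape, dtype=bool)
    bad_depth[county_r0 + 8:county_r0 + 12, county_c0 + 2:county_c0 + 6] = True
    bad_texture = np.zeros(grid.shape, dtype=bool)
    bad_texture[county_r0 + 14:county_r0 + 18, county_c0 + 2:county_c0 + 6] = True
    # plus far-field fallow beyond every buffer (top-left corner)
    far = np.zeros(grid.shape, dtype=bool)
    far[0:5, 0:5] = True
    for patch in (bad_climate, bad_depth, bad_texture, far):
        if (patch & fallow).any():
            raise GenerationError("distractor patches overlap target/ring rectangles")
        fallow |= patch

    codes = dict(LANDUSE_CODES)
    codes[d.crop_id] = 2
    lu_vals = np.zeros(grid.shape, dtype=np.int16)
    lu_vals[fallow] = codes["fallow_cropland"]
    # a cultivated block of the crop inside the county (not fallow)
    cult = np.zeros(grid.shape, dtype=bool)
    cult[county_r0 + 2:county_r0 + 20, county_c1 - 20:county_c1 - 2] = True
    cult &= ~fallow
    lu_vals[cult] = codes[d.crop_id]
    landuse = LandUseLayer(GridRaster(lu_vals, grid.cell_size_m, grid.origin_xy,
                                      kind="categorical"), codes)

    # --- climate: seeded ramps; requirement bounds cover ramp + noise -----
    cspec = ClimateSpec()
    climate = gen_climate(grid, seed=np.random.default_rng(seed).integers(2**31), spec=cspec)
    margin = cspec.noise_amplitude + 1.0
    precip_bounds = tuple(
        (cspec.precip_lo[m] - margin, cspec.precip_lo[m] + cspec.precip_range + margin)
        for m in range(12))
    tmin_bounds = tuple(
        (cspec.tmin_lo[m] - margin, cspec.tmin_lo[m] + cspec.tmin_range + margin)
        for m in range(12))
    tmax_bounds = tuple(
        (cspec.tmin_lo[m] - margin,
         cspec.tmin_lo[m] + cspec.tmin_range + cspec.tmax_spread + margin)
        for m in range(12))
    # poison month 0 precipitation on the climate distractor
    p0 = climate.precip[0].values
    p0[bad_climate] = precip_bounds[0][1] + 1000.0

    # --- soil ------------------------------------------------------------
    depth_vals = np.full(grid.shape, d.soil_depth_cm)
    depth_vals[bad_depth] = max(d.soil_depth_min_cm - 40.0, 0.0)
    tex_vals = np.full(grid.shape, d.texture_code, dtype=np.int16)
    bad_code = max(set(range(1, 13)) - set(d.allowed_textures))
    tex_vals[bad_texture] = bad_code
    soil = SoilLayers(
        depth=GridRaster(depth_vals, grid.cell_size_m, grid.origin_xy),
        texture=GridRaster(tex_vals, grid.cell_size_m, grid.origin_xy, kind="categorical"))

    # --- counties & acreage ----------------------------------------------
    counties, acreage = gen_counties(
        grid, d.county_tiles, d.crop_id, {d.center_tile: d.center_share},
        seed=np.random.default_rng(seed + 1).integers(2**31))

    requirement = CropRequirement(
        crop_id=d.crop_id,
        active_conditions=("precip", "tmin", "tmax", "soil_depth", "texture", "fallow"),
        precip_bounds=precip_bounds, tmin_bounds=tmin_bounds, tmax_bounds=tmax_bounds,
        soil_depth_min_cm=d.soil_depth_min_cm,
        allowed_textures=frozenset(d.allowed_textures))
    yields = YieldRecord(d.crop_id, counties[d.center_tile].state, d.yield_kg_per_ha)
    losses = LossChain(d.crop_id, d.farm_loss, d.retail_loss, d.consumer_loss,
                       d.cups_per_kg)

    # --- closed-form expectations ----------------------------------------
    target = np.zeros(grid.shape, dtype=bool)
    target[r0:r0 + h, c0:c0 + w] = True
    expected_masks, expected_area, expected_cups = {}, {}, {}
    cum = target.copy()
    cum_cells = target_cells
    for k, b in enumerate(d.buffers_km):
        if k > 0:
            cum = cum | ring_masks[k - 1]
            cum_cells += ring_cells[k - 1]
        expected_masks[float(b)] = Mask(cum.copy(), grid.cell_size_m, grid.origin_xy)
        # closed form, independent of the pipeline's own chain functions
        area = cum_cells * (grid.cell_size_m ** 2 / 10_000.0)
        expected_area[float(b)] = area
        consumer_kg = (area * d.yield_kg_per_ha
                       * (1 - d.farm_loss) * (1 - d.retail_loss) * (1 - d.consumer_loss))
        expected_cups[float(b)] = consumer_kg * d.cups_per_kg / d.population / 365.0

    return TruthCase(
        seed=seed, design=d, climate=climate, soil=soil, landuse=landuse,
        counties=counties, acreage=acreage, requirement=requirement,
        yields=yields, losses=losses, population=d.population,
        expected_masks=expected_masks, expected_area_ha=expected_area,
        expected_cups=expected_cups)
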