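"""End-to-end orchestration: centers -> scenarios -> suitability -> availability.

The in-memory entry point is :func:`run_crop_scenarios`; the file-based
entry point used by the CLI is :func:`run_pipeline` with a
:class:`RunConfig`. Every run produces a machine-readable log recording
the configuration, each overlay's filter cascade (surviving cell count per
condition), and per-scenario results, so the binding constraint of every
model is auditable.

When a crop has several production centers, their scenario regions are
united before area accounting (a cell suitable in two centers' buffers is
counted once); each cell is attributed to the highest-share center whose
region covers it, so state-specific yields apply per center without double
counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import io as cio
from .availability import (LossChain, ScenarioResult, YieldRecord, loss_adjust,
                           per_capita_cups, production_from_area, scenario_table)
from .errors import PipelineError
from .production_centers import (STANDARD_BUFFERS_KM, CountyRecord,
                                 expand_center, identify_centers)
from .raster_core import ClimateStack, LandUseLayer, Mask, SoilLayers, mask_area_ha
from .suitability import CropRequirement, DerivedBounds, evaluate_suitability
from .synthetic_data import TruthCase


@dataclass
class RunConfig:
    """File-level configuration for an end-to-end run.

    ``yields``/``losses``/``acreage`` are CSV paths; climate/soil/land-use
    rasters are ESRI ASCII grids (12 files per climate variable);
    ``county_label_map`` maps county ids to integer codes of the county
    label raster. Buffers must be sorted ascending and include 0.
    """

    crop_ids: Sequence[str]
    acreage_csv: str
    county_labels_asc: str
    county_label_map: Mapping[str, int]
    requirements_yaml: str
    yields_csv: str
    losses_csv: str
    population: float
    precip_asc: Sequence[str] = ()
    tmin_asc: Sequence[str] = ()
    tmax_asc: Sequence[str] = ()
    soil_depth_asc: str | None = None
    soil_texture_asc: str | None = None
    landuse_asc: str | None = None
    landuse_codes: Mapping[str, int] = field(default_factory=dict)
    year_range: Sequence[int] = tuple(range(2002, 2013))
    threshold: float = 0.10
    buffers_km: Sequence[float] = STANDARD_BUFFERS_KM
    clip_mask_asc: str | None = None
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self):
        b = list(self.buffers_km)
        if b != sorted(b) or (b and b[0] != 0):
            raise PipelineError("config", "buffer list must be ascending and start at 0")


def run_crop_scenarios(
    crop_id: str,
    counties: Sequence[CountyRecord],
    climate: ClimateStack | None,
    soil: SoilLayers | None,
    landuse: LandUseLayer | None,
    requirement: CropRequirement,
    yields_by_state: Mapping[str, YieldRecord] | YieldRecord,
    losses: LossChain,
    population: float,
    year_range: Sequence[int] = tuple(range(2002, 2013)),
    threshold: float = 0.10,
    buffers_km: Sequence[float] = STANDARD_BUFFERS_KM,
    clip: Mask | None = None,
    derived: DerivedBounds | None = None,
    log: dict | None = None,
) -> list[ScenarioResult]:
    """Scenario ladder for one crop: identify centers, expand, overlay, convert.

    Results are cumulative in buffer distance by construction (regions
    nest). Raises :class:`PipelineError` naming the failing stage.
    """
    log = log if log is not None else {}
    try:
        centers = identify_centers(counties, crop_id, year_range, threshold)
    except Exception as e:
        raise PipelineError("centers", str(e)) from e
    log["centers"] = [
        {"members": sorted(c.member_county_ids), "share": c.share, "state": c.state}
        for c in centers]
    if not centers:
        raise PipelineError("centers", f"no production center reaches share {threshold}"
                                       f" for crop {crop_id}")

    results = []
    log["scenarios"] = {}
    for b in buffers_km:
        try:
            regions = [expand_center(c, b, clip=clip) for c in centers]
        except Exception as e:
            raise PipelineError("expand", str(e)) from e
        union = regions[0].mask
        for r in regions[1:]:
            union = union | r.mask
        cascade: dict[str, int] = {}
        try:
            suitable = evaluate_suitability(climate, soil, landuse, requirement,
                                            union, derived=derived, cascade=cascade)
        except Exception as e:
            raise PipelineError("suitability", str(e)) from e
        log["scenarios"][b] = {"cascade": cascade}

        # attribute each suitable cell to the highest-share center covering it
        total_area = 0.0
        consumer_kg = 0.0
        farm_total = 0.0
        claimed = np.zeros(union.shape, dtype=bool)
        for center, region in zip(centers, regions):
            cells = suitable.values & region.mask.values & ~claimed
            claimed |= region.mask.values
            area = Mask(cells, union.cell_size_m, union.origin_xy)
            area_ha = mask_area_ha(area)
            if isinstance(yields_by_state, YieldRecord):
                yrec = yields_by_state
            else:
                try:
                    yrec = yields_by_state[center.state]
                except KeyError as e:
                    raise PipelineError(
                        "availability", f"no yield for crop {crop_id} in state "
                                        f"{center.state}") from e
            farm = production_from_area(area_ha, yrec)
            farm_total += farm
            consumer_kg += loss_adjust(farm, losses)
            total_area += area_ha
        cups = per_capita_cups(consumer_kg, losses, population)
        results.append(ScenarioResult(
            crop_id=crop_id, buffer_km=float(b), suitable_area_ha=total_area,
            production_kg_farm=farm_total, cups_per_capita_day=cups))
        log["scenarios"][b]["suitable_area_ha"] = total_area
        log["scenarios"][b]["cups_per_capita_day"] = cups
    return results


def run_truth_case(case: TruthCase, buffers_km: Sequence[float] | None = None,
                   log: dict | None = None) -> list[ScenarioResult]:
    """Run the full pipeline on a synthetic truth bundle."""
    return run_crop_scenarios(
        crop_id=case.design.crop_id,
        counties=case.counties,
        climate=case.climate, soil=case.soil, landuse=case.landuse,
        requirement=case.requirement,
        yields_by_state=case.yields, losses=case.losses,
        population=case.population,
        buffers_km=buffers_km if buffers_km is not None else case.design.buffers_km,
        log=log)


def run_pipeline(config: RunConfig) -> dict:
    """File-based end-to-end run; writes reports and a JSON run manifest.

    Returns a bundle with the per-crop results, the two report tables
    (area in ha and cup-eq/person/day, crops x buffers with a Total row),
    and the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {"config": {k: str(v) for k, v in vars(config).items()}, "crops": {}}

    try:
        acreage = cio.read_acreage_csv(config.acreage_csv)
        labels = cio.read_ascii_grid(config.county_labels_asc, kind="categorical")
        requirements = cio.read_requirements_yaml(config.requirements_yaml)
        yields = cio.read_yields_csv(config.yields_csv)
        losses = cio.read_losses_csv(config.losses_csv)
    except Exception as e:
        raise PipelineError("load", str(e)) from e

    climate = None
    if config.precip_asc:
        climate = ClimateStack(
            precip=[cio.read_ascii_grid(p) for p in config.precip_asc],
            tmin=[cio.read_ascii_grid(p) for p in config.tmin_asc],
            tmax=[cio.read_ascii_grid(p) for p in config.tmax_asc])
    soil = None
    if config.soil_depth_asc:
        soil = SoilLayers(
            depth=cio.read_ascii_grid(config.soil_depth_asc),
            texture=cio.read_ascii_grid(config.soil_texture_asc, kind="categorical"))
    landuse = None
    if config.landuse_asc:
        landuse = LandUseLayer(
            cio.read_ascii_grid(config.landuse_asc, kind="categorical"),
            dict(config.landuse_codes))
    clip = cio.read_mask(config.clip_mask_asc) if config.clip_mask_asc else None

    all_results: list[ScenarioResult] = []
    for crop_id in config.crop_ids:
        counties = cio.counties_from_tables(acreage, labels, config.county_label_map,
                                            crop_id)
        if crop_id not in requirements:
            raise PipelineError("suitability",
                                f"no requirement block for crop {crop_id} in "
                                f"{config.requirements_yaml}")
        crop_yields = {s: rec for (c, s), rec in yields.items() if c == crop_id}
        if crop_id not in losses:
            raise PipelineError("availability", f"no loss chain for crop {crop_id} in "
                                                f"{config.losses_csv}")
        crop_log: dict = {}
        all_results.extend(run_crop_scenarios(
            crop_id, counties, climate, soil, landuse, requirements[crop_id],
            crop_yields, losses[crop_id], config.population,
            year_range=config.year_range, threshold=config.threshold,
            buffers_km=config.buffers_km, clip=clip, log=crop_log))
        log["crops"][crop_id] = crop_log

    area_table = scenario_table(all_results, value="suitable_area_ha")
    cups_table = scenario_table(all_results, value="cups_per_capita_day")
    area_table.to_csv(out / "suitable_area_ha.csv")
    cups_table.to_csv(out / "cups_per_capita_day.csv")
    cio.write_json(log, out / "run_manifest.json")
    return {"results": all_results, "area_table": area_table,
            "cups_table": cups_table, "log": log}
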