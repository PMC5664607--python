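"""Requirement parameterisation and the boolean overlay."""

import numpy as np
import pytest

from cropsuit import (ClimateStack, CropRequirement, GridRaster, LandUseLayer, Mask,
                      SoilLayers, crop_clusters, derive_bounds, evaluate_suitability,
                      mask_area_ha)
from cropsuit.errors import (AlignmentError, ArgumentError, ConfigurationError,
                             EmptyCropError, EmptyZoneError)

SHAPE = (30, 40)
CELL = 30.0


def raster(values, kind="continuous", nodata=None):
    return GridRaster(np.asarray(values, dtype=float if kind == "continuous" else int),
                      CELL, nodata=nodata, kind=kind)


def mask(values):
    return Mask(np.asarray(values, dtype=bool), CELL)


def full_mask():
    return mask(np.ones(SHAPE))


def uniform_climate(p=50.0, tlo=5.0, thi=20.0):
    return ClimateStack(
        precip=[raster(np.full(SHAPE, p)) for _ in range(12)],
        tmin=[raster(np.full(SHAPE, tlo)) for _ in range(12)],
        tmax=[raster(np.full(SHAPE, thi)) for _ in range(12)])


def uniform_soil(depth=100.0, texture=4):
    return SoilLayers(depth=raster(np.full(SHAPE, depth)),
                      texture=raster(np.full(SHAPE, texture), kind="categorical"))


def all_fallow():
    return LandUseLayer(raster(np.ones(SHAPE), kind="categorical"),
                        {"other": 0, "fallow_cropland": 1})


def wide_bounds(lo, hi):
    return tuple((lo, hi) for _ in range(12))


class TestDeriveBounds:
    def test_uniform_field_collapses_bounds(self):
        db = derive_bounds(uniform_climate(p=12.5), full_mask())
        assert all(b == (12.5, 12.5) for b in db.bounds["precip"])

    def test_ramp_zone_bounds_are_corner_values(self):
        ramp = np.tile(np.linspace(0, 39, 40), (30, 1))
        stack = ClimateStack(precip=[raster(ramp)] * 12,
                             tmin=[raster(ramp)] * 12,
                             tmax=[raster(ramp + 1)] * 12)
        zone_vals = np.zeros(SHAPE, dtype=bool)
        zone_vals[5:10, 10:20] = True
        db = derive_bounds(stack, mask(zone_vals))
        assert db.bounds["precip"][0] == (10.0, 19.0)

    def test_matches_exhaustive_scan(self, rng):
        stack = ClimateStack(
            precip=[raster(rng.uniform(0, 100, SHAPE)) for _ in range(12)],
            tmin=[raster(rng.uniform(-10, 0, SHAPE)) for _ in range(12)],
            tmax=[raster(rng.uniform(1, 30, SHAPE)) for _ in range(12)])
        zone_vals = rng.random(SHAPE) < 0.2
        db = derive_bounds(stack, mask(zone_vals))
        for var in ("precip", "tmin", "tmax"):
            for m in range(12):
                vals = getattr(stack, var)[m].values[zone_vals]
                assert db.bounds[var][m] == pytest.approx((vals.min(), vals.max()))

    def test_every_in_zone_cell_satisfies_its_own_bounds(self, rng):
        stack = ClimateStack(
            precip=[raster(rng.uniform(0, 100, SHAPE)) for _ in range(12)],
            tmin=[raster(np.full(SHAPE, 0.0)) for _ in range(12)],
            tmax=[raster(np.full(SHAPE, 9.0)) for _ in range(12)])
        zone_vals = rng.random(SHAPE) < 0.3
        zone = mask(zone_vals)
        db = derive_bounds(stack, zone)
        req = CropRequirement("c", ("precip", "tmin", "tmax"))
        out = evaluate_suitability(stack, None, None, req, zone, derived=db)
        np.testing.assert_array_equal(out.values, zone_vals)

    def test_empty_zone_raises(self):
        with pytest.raises(EmptyZoneError):
            derive_bounds(uniform_climate(), mask(np.zeros(SHAPE)))


class TestCropClusters:
    def _landuse(self, crop_cells):
        vals = np.zeros(SHAPE, dtype=int)
        vals[crop_cells] = 2
        return LandUseLayer(raster(vals, kind="categorical"),
                            {"other": 0, "fallow_cropland": 1, "beans": 2})

    def test_single_component_returned_whole(self):
        cells = np.zeros(SHAPE, dtype=bool)
        cells[3:8, 3:8] = True
        lu = self._landuse(cells)
        out = crop_clusters(lu, "beans")
        np.testing.assert_array_equal(out.values, cells)

    def test_prefix_of_largest_components_covers_95_percent(self):
        # components of 60, 30, 8, 2 cells: 60+30 = 90 < 95, +8 = 98 >= 95
        cells = np.zeros(SHAPE, dtype=bool)
        cells[0:6, 0:10] = True       # 60
        cells[10:13, 0:10] = True     # 30
        cells[20:21, 0:8] = True      # 8
        cells[25:26, 0:2] = True      # 2
        lu = self._landuse(cells)
        out = crop_clusters(lu, "beans", coverage=0.95)
        assert out.count() == 98
        assert not out.values[25, 0]  # smallest component excluded

    def test_full_coverage_returns_all_crop_cells(self):
        cells = np.zeros(SHAPE, dtype=bool)
        cells[0:2, 0:3] = cells[10:11, 10:14] = True
        out = crop_clusters(self._landuse(cells), "beans", coverage=1.0)
        np.testing.assert_array_equal(out.values, cells)

    def test_no_crop_cells_raises(self):
        with pytest.raises(EmptyCropError):
            crop_clusters(self._landuse(np.zeros(SHAPE, dtype=bool)), "beans")


class TestEvaluateSuitability:
    def test_self_consistent_bounds_reproduce_region(self):
        stack = uniform_climate()
        region_vals = np.zeros(SHAPE, dtype=bool)
        region_vals[5:15, 5:25] = True
        region = mask(region_vals)
        db = derive_bounds(stack, region)
        req = CropRequirement("c", ("precip", "tmin", "tmax", "soil_depth",
                                    "texture", "fallow"),
                              soil_depth_min_cm=50.0, allowed_textures=frozenset({4}))
        out = evaluate_suitability(stack, uniform_soil(), all_fallow(), req,
                                   region, derived=db)
        np.testing.assert_array_equal(out.values, region_vals)

    def test_constructed_rectangle_is_recovered_exactly(self):
        # exactly one 20x30 rectangle satisfies all layers -> 600 cells, 54 ha
        stack = uniform_climate(p=50.0)
        rect = np.zeros(SHAPE, dtype=bool)
        rect[5:25, 5:35] = True
        precip = np.where(rect, 50.0, 500.0)
        stack = ClimateStack(precip=[raster(precip)] * 12, tmin=stack.tmin,
                             tmax=stack.tmax)
        req = CropRequirement("c", ("precip", "tmin", "tmax", "soil_depth", "texture",
                                    "fallow"),
                              precip_bounds=wide_bounds(0, 100),
                              tmin_bounds=wide_bounds(-50, 50),
                              tmax_bounds=wide_bounds(-50, 50),
                              soil_depth_min_cm=50.0, allowed_textures=frozenset({4}))
        out = evaluate_suitability(stack, uniform_soil(), all_fallow(), req, full_mask())
        np.testing.assert_array_equal(out.values, rect)
        assert mask_area_ha(out) == pytest.approx(600 * 0.09)  # 54 ha

    def test_landuse_only_model_ignores_climate_and_soil(self):
        # indoor-crop style: only the land-use condition is active
        lu_vals = np.zeros(SHAPE, dtype=int)
        lu_vals[0:4, 0:4] = 1
        lu = LandUseLayer(raster(lu_vals, kind="categorical"),
                          {"other": 0, "fallow_cropland": 1})
        req = CropRequirement("mushroom_style", ("fallow",))
        region_vals = np.ones(SHAPE, dtype=bool)
        region_vals[0, 0] = False
        out = evaluate_suitability(None, None, lu, req, mask(region_vals))
        want = (lu_vals == 1) & region_vals
        np.testing.assert_array_equal(out.values, want)

    def test_adding_a_condition_never_gains_cells(self, rng):
        stack = ClimateStack(
            precip=[raster(rng.uniform(0, 100, SHAPE)) for _ in range(12)],
            tmin=[raster(np.full(SHAPE, 5.0))] * 12,
            tmax=[raster(np.full(SHAPE, 20.0))] * 12)
        soil = SoilLayers(depth=raster(rng.uniform(0, 200, SHAPE)),
                          texture=raster(rng.integers(1, 13, SHAPE), kind="categorical"))
        params = {"precip": {"precip_bounds": wide_bounds(20, 80)},
                  "soil_depth": {"soil_depth_min_cm": 60.0},
                  "texture": {"allowed_textures": frozenset({1, 2, 3, 4, 5, 6})}}
        prev = None
        for extra in (["precip"], ["precip", "soil_depth"],
                      ["precip", "soil_depth", "texture"]):
            kwargs = {k: v for c in extra for k, v in params[c].items()}
            req = CropRequirement("c", tuple(["fallow"] + extra), **kwargs)
            out = evaluate_suitability(stack, soil, all_fallow(), req, full_mask())
            if prev is not None:
                assert out.count() <= prev
            prev = out.count()

    def test_widening_bounds_never_loses_cells(self, rng):
        precip = [raster(rng.uniform(0, 100, SHAPE)) for _ in range(12)]
        stack = ClimateStack(precip=precip,
                             tmin=[raster(np.full(SHAPE, 5.0))] * 12,
                             tmax=[raster(np.full(SHAPE, 20.0))] * 12)
        narrow = CropRequirement("c", ("precip",), precip_bounds=wide_bounds(40, 60))
        wide = CropRequirement("c", ("precip",), precip_bounds=wide_bounds(20, 80))
        n = evaluate_suitability(stack, None, None, narrow, full_mask()).count()
        w = evaluate_suitability(stack, None, None, wide, full_mask()).count()
        assert w >= n

    def test_smaller_region_gives_subset(self, rng):
        stack = uniform_climate()
        req = CropRequirement("c", ("precip",), precip_bounds=wide_bounds(0, 100))
        r2_vals = rng.random(SHAPE) < 0.6
        r1_vals = r2_vals & (rng.random(SHAPE) < 0.5)
        out1 = evaluate_suitability(stack, None, None, req, mask(r1_vals))
        out2 = evaluate_suitability(stack, None, None, req, mask(r2_vals))
        assert not (out1.values & ~out2.values).any()

    def test_nodata_in_active_layer_is_unsuitable(self):
        precip_vals = np.full(SHAPE, 50.0)
        precip_vals[2, 2] = -9999.0
        stack = ClimateStack(
            precip=[raster(precip_vals, nodata=-9999.0)] + [raster(np.full(SHAPE, 50.0))] * 11,
            tmin=[raster(np.full(SHAPE, 5.0))] * 12,
            tmax=[raster(np.full(SHAPE, 20.0))] * 12)
        req = CropRequirement("c", ("precip",), precip_bounds=wide_bounds(-1e6, 1e6))
        out = evaluate_suitability(stack, None, None, req, full_mask())
        assert not out.values[2, 2]
        assert out.count() == SHAPE[0] * SHAPE[1] - 1

    def test_cascade_records_surviving_counts(self):
        stack = uniform_climate()
        req = CropRequirement("c", ("precip", "fallow"),
                              precip_bounds=wide_bounds(0, 100))
        cascade = {}
        evaluate_suitability(stack, None, all_fallow(), req, full_mask(),
                             cascade=cascade)
        assert list(cascade) == ["region", "fallow", "precip"]
        assert cascade["region"] >= cascade["fallow"] >= cascade["precip"]

    def test_misaligned_layers_rejected(self):
        stack = uniform_climate()
        req = CropRequirement("c", ("precip",), precip_bounds=wide_bounds(0, 100))
        bad_region = Mask(np.ones((10, 10), dtype=bool), CELL)
        with pytest.raises(AlignmentError):
            evaluate_suitability(stack, None, None, req, bad_region)

    def test_inactive_condition_with_bounds_warns(self):
        with pytest.warns(UserWarning, match="inactive"):
            CropRequirement("c", ("fallow",), precip_bounds=wide_bounds(0, 1))

    def test_requirement_needs_at_least_one_condition(self):
        with pytest.raises(ConfigurationError):
            CropRequirement("c", ())

    def test_invalid_bound_order_rejected(self):
        with pytest.raises(ConfigurationError):
            CropRequirement("c", ("precip",), precip_bounds=wide_bounds(10, 5))
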