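"""Production-center identification and buffer scenarios."""

import numpy as np
import pytest

from cropsuit import (CountyRecord, Mask, expand_center, identify_centers,
                      mask_area_ha, mean_national_share)
from cropsuit.errors import ArgumentError, DegenerateDataError
from cropsuit.production_centers import derive_adjacency

YEARS = list(range(2002, 2013))


def county(cid, acreage, tile, grid=(12, 12), tiles=(3, 3), state="SY"):
    """County on a rectangular tile of a small shared grid."""
    nr, nc = tiles
    th, tw = grid[0] // nr, grid[1] // nc
    r, c = divmod(tile, nc)
    vals = np.zeros(grid, dtype=bool)
    vals[r * th:(r + 1) * th, c * tw:(c + 1) * tw] = True
    return CountyRecord(cid, state, Mask(vals, 30.0),
                        {y: float(acreage) for y in YEARS})


class TestMeanNationalShare:
    def test_single_producer_holds_everything(self):
        c = county("only", 100.0, 0)
        assert mean_national_share(c, [c], YEARS) == pytest.approx(1.0)

    def test_riverside_style_dominant_county(self):
        # built to hold 55% of national acreage
        cs = [county("riverside", 55.0, 0), county("b", 30.0, 1), county("c", 15.0, 2)]
        assert mean_national_share(cs[0], cs, YEARS) == pytest.approx(0.55)

    def test_four_county_table_matches_spreadsheet(self):
        # hand-computed: means 10, 20, 30, 40 -> shares .1, .2, .3, .4
        cs = [county(f"c{i}", 10.0 * (i + 1), i) for i in range(4)]
        shares = [mean_national_share(c, cs, YEARS) for c in cs]
        assert shares == pytest.approx([0.1, 0.2, 0.3, 0.4])
        assert sum(shares) == pytest.approx(1.0, abs=1e-9)

    def test_zero_national_acreage_is_degenerate(self):
        c = county("z", 0.0, 0)
        with pytest.raises(DegenerateDataError):
            mean_national_share(c, [c], YEARS)


class UnionFind:
    """Independent grouping oracle."""

    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, i):
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a, b):
        self.parent[self.find(a)] = self.find(b)

    def groups(self):
        out = {}
        for i in self.parent:
            out.setdefault(self.find(i), set()).add(i)
        return {frozenset(g) for g in out.values()}


class TestIdentifyCenters:
    def test_no_eligible_counties_gives_empty_list(self):
        cs = [county(f"c{i}", 5.0, i) for i in range(9)]  # all share 1/9 < 0.2
        assert identify_centers(cs, "crop", YEARS, threshold=0.2) == []

    def test_sweet_potato_style_three_centers(self):
        # four abutting counties each individually above the 10% threshold,
        # two isolated eligible counties, remainder below threshold
        tiles = dict(grid=(12, 12), tiles=(3, 4))
        cs = [
            county("johnston", 13.0, 0, **tiles), county("nash", 12.0, 1, **tiles),
            county("sampson", 11.0, 4, **tiles), county("wilson", 10.0, 5, **tiles),
            county("calhoun", 12.0, 2, **tiles), county("merced", 11.0, 7, **tiles),
            county("o1", 6.0, 3, **tiles), county("o2", 5.0, 6, **tiles),
            county("o3", 5.0, 8, **tiles), county("o4", 5.0, 9, **tiles),
            county("o5", 5.0, 10, **tiles), county("o6", 5.0, 11, **tiles),
        ]  # national mean = 100
        centers = identify_centers(cs, "sweet_potatoes", YEARS, threshold=0.10,
                                   adjacency=[("johnston", "nash"), ("johnston", "sampson"),
                                              ("nash", "wilson"), ("sampson", "wilson")])
        assert len(centers) == 3
        groups = {c.member_county_ids for c in centers}
        assert groups == {frozenset({"johnston", "nash", "sampson", "wilson"}),
                          frozenset({"calhoun"}), frozenset({"merced"})}
        nc = next(c for c in centers if len(c.member_county_ids) == 4)
        assert nc.share == pytest.approx(0.46)
        # sorted by descending share
        assert [round(c.share, 2) for c in centers] == [0.46, 0.12, 0.11]

    def test_grouping_matches_union_find_oracle(self, rng):
        for _ in range(20):
            cs = [county(f"c{i}", float(rng.uniform(0, 30)), i) for i in range(8)]
            pairs = [(f"c{a}", f"c{b}") for a in range(8) for b in range(a + 1, 8)
                     if rng.random() < 0.25]
            threshold = 0.10
            centers = identify_centers(cs, "crop", YEARS, threshold, adjacency=pairs)
            shares = {c.county_id: mean_national_share(c, cs, YEARS) for c in cs}
            eligible = {cid for cid, s in shares.items() if s >= threshold}
            uf = UnionFind(eligible)
            for a, b in pairs:
                if a in eligible and b in eligible:
                    uf.union(a, b)
            assert {c.member_county_ids for c in centers} == uf.groups()

    def test_result_independent_of_county_order(self, rng):
        cs = [county(f"c{i}", float(10 + i), i) for i in range(6)]
        pairs = [("c0", "c1"), ("c2", "c3")]
        a = identify_centers(cs, "crop", YEARS, 0.1, adjacency=pairs)
        perm = [cs[i] for i in rng.permutation(6)]
        b = identify_centers(perm, "crop", YEARS, 0.1, adjacency=pairs)
        assert [c.member_county_ids for c in a] == [c.member_county_ids for c in b]

    def test_raising_threshold_never_adds_centers(self):
        cs = [county(f"c{i}", float(10 * (i + 1)), i) for i in range(4)]
        n_low = sum(len(c.member_county_ids)
                    for c in identify_centers(cs, "crop", YEARS, 0.1))
        n_high = sum(len(c.member_county_ids)
                     for c in identify_centers(cs, "crop", YEARS, 0.3))
        assert n_high <= n_low
        assert identify_centers(cs, "crop", YEARS, 0.95) == []

    def test_derived_adjacency_is_rook_not_queen(self):
        # tiles 0 and 1 share an edge; tiles 0 and 4 touch only at a corner
        cs = [county("a", 20.0, 0), county("b", 20.0, 1), county("d", 20.0, 4)]
        pairs = derive_adjacency(cs)
        assert frozenset({"a", "b"}) in pairs
        assert frozenset({"a", "d"}) not in pairs


class TestExpandCenter:
    def _center(self):
        cs = [county("a", 100.0, 4)]  # middle tile of 3x3
        return identify_centers(cs, "crop", YEARS, 0.1)[0]

    def test_zero_buffer_is_identity(self):
        c = self._center()
        region = expand_center(c, 0)
        np.testing.assert_array_equal(region.mask.values, c.mask.values)

    def test_small_buffer_area_matches_brute_force_dilation(self):
        from test_raster_core import brute_dilate
        c = self._center()
        with pytest.warns(UserWarning):
            region = expand_center(c, 0.06)  # 60 m at 30 m cells
        want = brute_dilate(c.mask.values, 2.0)
        np.testing.assert_array_equal(region.mask.values, want)

    def test_five_scenarios_are_nested_and_monotone(self):
        c = self._center()
        areas, prev = [], None
        for b in (0, 5, 10, 15, 20):
            region = expand_center(c, b)
            if prev is not None:
                assert ((prev.values & ~region.mask.values).sum()) == 0
            areas.append(mask_area_ha(region.mask))
            prev = region.mask
        assert areas == sorted(areas)

    def test_negative_buffer_rejected(self):
        with pytest.raises(ArgumentError):
            expand_center(self._center(), -5)
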