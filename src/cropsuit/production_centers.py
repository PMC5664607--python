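"""Production-center identification and buffer-expansion scenarios.

A production center is a county — or a group of abutting counties — holding
at least 10% of a crop's mean national harvested acreage over a reference
year range. Scenario regions enlarge a center's footprint by a fixed
distance from all sides (Euclidean dilation of its raster mask), giving the
standard ladder of 0, 5, 10, 15 and 20 km expansions.

"Abutting" uses rook (edge) contiguity of the county masks: corner-only
contact does not merge. Adjacency may also be supplied explicitly as a pair
list. Buffers are not clipped at any administrative border unless an
explicit clip mask is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import ArgumentError, DegenerateDataError
from .raster_core import Mask, dilate_mask, require_aligned

STANDARD_BUFFERS_KM = (0, 5, 10, 15, 20)
DEFAULT_SHARE_THRESHOLD = 0.10


@dataclass
class CountyRecord:
    """One county's footprint and harvested acreage history for one crop."""

    county_id: str
    state: str
    mask: Mask
    acreage_by_year: Mapping[int, float]

    def __post_init__(self):
        if any(a < 0 for a in self.acreage_by_year.values()):
            raise ArgumentError(f"negative acreage for county {self.county_id}")

    def mean_acreage(self, years: Sequence[int]) -> float:
        return float(np.mean([self.acreage_by_year.get(y, 0.0) for y in years]))


@dataclass
class ProductionCenter:
    """A maximal group of abutting threshold-eligible counties for one crop."""

    crop_id: str
    member_county_ids: frozenset[str]
    mask: Mask
    share: float
    state: str | None = None


@dataclass
class ScenarioRegion:
    """A center footprint expanded by ``buffer_km`` from all sides."""

    center: ProductionCenter
    buffer_km: float
    mask: Mask


def mean_national_share(county: CountyRecord, all_counties: Sequence[CountyRecord],
                        year_range: Sequence[int]) -> float:
    """County's fraction of mean national acreage over ``year_range``.

    Shares over all counties sum to 1. National and county means are taken
    over the same year set, with missing years counted as zero acreage.
    """
    years = list(year_range)
    if not years:
        raise ArgumentError("year_range must be non-empty")
    national = sum(c.mean_acreage(years) for c in all_counties)
    if national <= 0:
        raise DegenerateDataError("mean national acreage is zero over the year range")
    return county.mean_acreage(years) / national


def derive_adjacency(counties: Sequence[CountyRecord]) -> set[frozenset[str]]:
    """Edge-adjacent (rook) county pairs derived from their masks.

    Two counties abut iff some cell of one is edge-adjacent to a cell of
    the other.
    """
    if not counties:
        return set()
    require_aligned(*(c.mask for c in counties))
    shape = counties[0].mask.shape
    label = np.zeros(shape, dtype=int)
    for i, c in enumerate(counties, start=1):
        if np.any(label[c.mask.values]):
            raise ArgumentError("county masks must be pairwise disjoint")
        label[c.mask.values] = i
    pairs: set[frozenset[str]] = set()
    for a, b in ((label[:-1, :], label[1:, :]), (label[:, :-1], label[:, 1:])):
        touch = (a > 0) & (b > 0) & (a != b)
        for i, j in zip(a[touch], b[touch]):
            pairs.add(frozenset((counties[i - 1].county_id, counties[j - 1].county_id)))
    return pairs


def identify_centers(
    counties: Sequence[CountyRecord],
    crop_id: str,
    year_range: Sequence[int],
    threshold: float = DEFAULT_SHARE_THRESHOLD,
    adjacency: Iterable[tuple[str, str]] | None = None,
) -> list[ProductionCenter]:
    """Partition threshold-eligible counties into production centers.

    Counties with share >= ``threshold`` are grouped by connectivity under
    the (symmetric) abutting relation; each connected group becomes one
    center whose mask is the union of member masks and whose share is the
    sum of member shares. Centers are returned sorted by descending share.
    ``adjacency=None`` derives rook adjacency from the county masks.
    """
    shares = {c.county_id: mean_national_share(c, counties, year_range) for c in counties}
    eligible = [c for c in counties if shares[c.county_id] >= threshold]
    if not eligible:
        return []
    if adjacency is None:
        pairs = derive_adjacency(counties)
    else:
        pairs = {frozenset(p) for p in adjacency}
    g = nx.Graph()
    g.add_nodes_from(c.county_id for c in eligible)
    eligible_ids = set(g.nodes)
    for pair in pairs:
        a, b = tuple(pair)
        if a in eligible_ids and b in eligible_ids:
            g.add_edge(a, b)
    by_id = {c.county_id: c for c in counties}
    centers = []
    for group in nx.connected_components(g):
        members = sorted(group)
        mask_vals = np.zeros(by_id[members[0]].mask.shape, dtype=bool)
        for m in members:
            mask_vals |= by_id[m].mask.values
        ref = by_id[members[0]].mask
        states = {by_id[m].state for m in members}
        centers.append(ProductionCenter(
            crop_id=crop_id,
            member_county_ids=frozenset(members),
            mask=Mask(mask_vals, ref.cell_size_m, ref.origin_xy),
            share=sum(shares[m] for m in members),
            state=states.pop() if len(states) == 1 else None,
        ))
    return sorted(centers, key=lambda c: (-c.share, sorted(c.member_county_ids)))


def expand_center(center: ProductionCenter, buffer_km: float,
                  clip: Mask | None = None) -> ScenarioRegion:
    """Scenario region: the center mask dilated by ``buffer_km`` kilometres.

    Non-standard buffer distances are allowed with a warning; negative
    distances are an error. An optional ``clip`` mask intersects the result
    (e.g. to exclude water or out-of-state cells).
    """
    if buffer_km < 0:
        raise ArgumentError(f"buffer must be >= 0 km, got {buffer_km}")
    if buffer_km not in STANDARD_BUFFERS_KM:
        warnings.warn(f"non-standard buffer distance {buffer_km} km", stacklevel=2)
    mask = dilate_mask(center.mask, buffer_km * 1000.0)
    if clip is not None:
        mask = mask & clip
    return ScenarioRegion(center=center, buffer_km=buffer_km, mask=mask)
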