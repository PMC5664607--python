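# Methods

## Model

The core model is a deterministic boolean site-suitability overlay on a
single planar grid of square cells (row-major arrays, 0-based indices,
origin at the upper-left outer corner, cell size in metres). A cell is
suitable for a crop iff all of the crop's *active* conditions hold:

- membership in the analysis region (a production center or its buffer),
- land-use class = fallow cropland,
- for each of 12 months, precipitation within inclusive (low, high)
  bounds, and likewise minimum and maximum surface temperature,
- soil depth ≥ a crop minimum,
- soil texture class within an allowed set (12-class USDA texture
  triangle coding; site-specific codes are mapped onto it in config).

Only the conditions relevant to a crop participate — an indoor crop such
as Agaricus mushrooms is modelled with land use alone. There is no
continuous scoring, no irrigation layer (precipitation is the sole water
supply test, a deliberately conservative assumption recorded in run
metadata), and no crop-growth simulation.

Assumptions worth making explicit:

- All layers are pre-aligned to one grid; reprojection/resampling is an
  I/O concern outside the core (the core is projection-agnostic planar
  meters).
- nodata in any active layer makes a cell unsuitable (conservative: a
  cell must demonstrably satisfy every condition).
- Bound comparisons are inclusive, so cells that generated derived
  bounds always remain suitable.
- The condition order inside the overlay is fixed only for the audit
  log; conjunction makes the result order-invariant.

## Production centers and scenarios

For each crop, counties holding ≥ `threshold` (default 0.10) of mean
national harvested acreage over a reference year range (default
2002–2012, inclusive; missing years count as zero acreage) are eligible;
abutting eligible counties merge into one center. "Abut" is rook (edge)
contiguity of county masks — corner contact does not merge — matching the
common GIS contiguity reading; adjacency may also be supplied as an
explicit pair list. Centers are processed independently and their
results summed.

Buffer scenarios dilate the center mask by 0/5/10/15/20 km. Membership
is decided by cell-center Euclidean distance (inclusive), computed with
an exact Euclidean distance transform in cell units; a 1e-9 cell-unit
slack on the radius comparison absorbs float square-root representation
at exact-tie radii (e.g. a cell at exactly 60 m from a 30 m neighbour).
Cell-center membership differs from any-overlap membership by at most a
sub-cell sliver, negligible at 30–100 m cells against km-scale buffers.
Buffers are not clipped at administrative borders unless an explicit
clip mask is supplied (whether the original analysis clipped at
coastlines is unknowable from its description; the unclipped default is
the simpler, reproducible choice). When one crop has several centers,
scenario regions are united before area accounting so overlapping
buffers are never double counted; each suitable cell is attributed to
the highest-share center covering it, so state-specific yields apply
per center.

## Derived climate bounds

Where published growing-condition bounds are coarser than the raster
data, per-month bounds are derived as the zonal (min, max) of each
climate variable over a reference zone: the whole production center, or
— when crop-specific land-use data support it — the connected clusters
of cultivation cells that cumulatively cover ≥ 95 % of the crop's cells
(components sorted by size descending, ties broken by first-scan label;
the smallest prefix reaching coverage is used). The provenance
(`whole_center` vs `crop_clusters`) is a per-crop switch because the
original description applies the cluster rule only where high-resolution
crop-specific land use existed. Published bounds, when supplied, take
precedence over derived ones per variable.

## Crop screening

The nutrient-density score defaults to the sum over {fiber, calcium,
magnesium, potassium} of percent-of-daily-reference per serving. The
exact published index this stands in for is not reproducible from its
description, so the aggregator (sum/mean), nutrient set, reference
amounts and cutoff are all configurable; default references are adult
daily values (28 g fiber, 1300 mg Ca, 420 mg Mg, 4700 mg K) and the
default cutoff is the top decile of supplied scores. Trend screening
fits an ordinary-least-squares slope of value on calendar year over the
most recent five years present in each series and requires strictly
positive slopes for both consumption and production. "Most recent five
year period" is read as the last five calendar years present.

## Availability chain

Cup-equivalents per person per day =
`area_ha × yield_kg_per_ha × (1−l_farm)(1−l_retail)(1−l_consumer) ×
cups_per_kg / population / 365`.

The loss-adjusted food availability accounting structure (primary→retail
conversion, nonedible share, retail and consumer loss) is collapsed into
three multiplicative fractions in [0, 1) plus one cups-per-kg factor per
crop; the factors are inputs, not constants of the package. A 365-day
year is used throughout (leap-day handling is immaterial at the reported
precision). Report tables sum a Total row at full precision; rounding
(areas to 0.1 × 10³ ha, availability to 0.1 × 10⁻³ cups) happens only at
presentation via `format_report`.

The published national per-crop tables are shipped in
`cropsuit.reference_tables` as inputs for internal-consistency checks
and report formatting; the package does not recompute their absolute
values, which depend on national data archives that cannot ship with
the code. One rounding artifact is worth noting: the published
no-expansion per-crop availability column sums to 43.7 × 10⁻³ cups
against a printed Total of 43.6 × 10⁻³ (one-decimal rounding of the
per-crop cells), and the mushroom-omission share of the no-expansion
cups column evaluates to ≈ 2.8 % from the printed cells, slightly below
the 3–14 % range stated alongside them; both totals were evidently
computed before rounding. The package therefore asserts exactness only
where the printed columns are self-consistent.

## Synthetic data

The generators emulate the *structure* of the real inputs — planar
grid-aligned rasters, smooth monthly climate fields (deterministic ramps
plus seeded uniform noise; max-temperature spread chosen so tmin ≤ tmax
always holds), categorical soil and land-use fields, rectangular-tile
county maps, and acreage tables whose designated counties hold exact
mean national shares with seeded year-to-year variation that averages
out. They make no attempt at distributional realism (no spatial
autocorrelation structure of real climate normals, no real county
geometries, no yield variability). Passing tests therefore demonstrate
the pipeline's arithmetic and geometric correctness, not calibration
against real landscapes.

General-purpose generators default to a 300 × 300 grid at 30 m
resolution, the working resolution of the analysis. Ground-truth cases
default to 100 m cells on a 500 × 500 grid (50 km × 50 km): the full
0–20 km buffer ladder does not fit in a 9 km-wide 30 m grid, and a 30 m
grid wide enough for 20 km buffers (> 1300² cells × 36 monthly layers)
would buy no additional coverage of the code paths. Ring rectangles are
placed at whole-cell horizontal offsets from the center county's edge,
within the county's row span, so every distance is exactly
`offset × cell_size` and buffer membership is decidable in closed form;
expected areas are cell counts × cell area and expected cups follow the
availability chain analytically, never through the pipeline under test.
Distractor fallow patches each fail exactly one condition (poisoned
month-1 precipitation, shallow soil, disallowed texture, or distance
beyond every buffer), so a pipeline that skipped any single condition
would fail recovery. A single run-level seed is fanned out per layer;
identical seeds give bit-identical bundles.

## Numerical choices

- Dilation radius comparison: inclusive, with 1e-9 cell-unit slack (see
  above); the test oracle uses exact integer squared distances.
- Cluster-coverage prefix: cumulative count compared with
  `coverage × total − 1e-9` to keep exact-fraction designs (e.g. 98 of
  100 cells at 95 %) stable under float multiplication.
- Trend slope: closed-form normal equation on centered years, exact for
  the short series involved.
- Shares: computed as ratios of means over a common year set; they sum
  to 1 by construction.
- Degenerate inputs raise typed errors rather than returning sentinel
  values: empty zones, all-identical years, zero national acreage, loss
  fractions ≥ 1, non-positive population, missing crop × buffer report
  cells.

## Problem sizes

The test suite runs the full pipeline on 25+ seeded ground-truth cases
(500 × 500 cells, 36 monthly climate layers each) plus brute-force
oracle comparisons on grids ≤ 40 × 40; the acceptance script runs one
full case per invocation. These sizes exercise every code path at exact
tolerances while keeping a complete run in the tens of seconds on one
core.

## Known limitations

- No vector (polygon) geometry: counties, centers and buffers are raster
  masks; sub-cell area integration is out of scope.
- No reprojection: all inputs must share one grid.
- Climate realism is out of scope for the generators; calibration claims
  about real landscapes cannot be made from these tests.
- The availability chain assumes equal national distribution of new
  supply and ignores prices, trade and demand response.
- Published per-crop growing-condition parameter values are handled as a
  config schema (YAML), not asserted: the original appendix values are
  not available in the source text.
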