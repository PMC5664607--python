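# cropsuit

Raster site-suitability and food-availability modelling for fruit and
vegetable (F&V) crops around national production centers.

## The problem

Most specialty F&V crops in the US are grown in a handful of concentrated
production centers — counties (or groups of abutting counties) holding a
large share of national harvested acreage — because supply-chain
infrastructure co-locates with production. If demand for nutrient-dense
F&V rose, how much *additional* suitable cropland exists in and around
those centers, and how much food would it supply per person?

`cropsuit` answers this with a reproducible pipeline for analysts working
at the intersection of agricultural land use and food systems:

1. **Crop screening** — score candidate foods on fiber, calcium,
   magnesium and potassium per serving (percent of daily reference,
   summed), and keep those with positive ordinary-least-squares trends of
   both consumption and production over the most recent five years.
2. **Production centers** — counties with ≥ 10 % of mean national
   harvested acreage; abutting eligible counties (rook contiguity) merge
   into one center.
3. **Buffer scenarios** — each center footprint is expanded 0, 5, 10, 15
   and 20 km from all sides (Euclidean dilation of its raster mask),
   giving five nested analysis regions.
4. **Site suitability** — a boolean overlay on a common 30 m grid: a cell
   is suitable iff *every* active crop condition holds — fallow cropland
   land use, monthly precipitation and min/max temperature within
   per-month bounds, minimum soil depth, allowed soil texture class.
   Bounds may be published values or derived from the climate range of
   the center (or of the clusters covering ≥ 95 % of the crop's
   cultivated cells).
5. **Availability** — suitable area A (ha) becomes cup-equivalents per
   person per day through a linear chain:

   ```
   cups/person/day = A · Y · (1-l_f)(1-l_r)(1-l_c) · k / (P · 365)
   ```

   with state yield Y (kg/ha), farm/retail/consumer loss fractions
   l_f, l_r, l_c, cup conversion k (cup-eq/kg) and population P.

Results are reported cumulatively across buffers in crops × scenario
tables with an exact Total row, mirroring the published national tables
stored in `cropsuit.reference_tables`.

The national input archives (PRISM-style climate normals, gridded soil
survey, cropland data layer, agricultural census) are not redistributable
here, so the package ships a first-class synthetic-data module that
emulates their structure on a planar grid with closed-form ground truth.

## Worked example

Generate a synthetic ground-truth bundle and run the full pipeline on it:

```python
import cropsuit as cs

case = cs.gen_truth_case(seed=1)          # 500x500 grid, 100 m cells
for r in cs.run_truth_case(case):
    print(f"{r.buffer_km:4.0f} km  {r.suitable_area_ha:7.1f} ha  "
          f"{r.cups_per_capita_day:.6f} cups/person/day")
```

prints

```
   0 km    600.0 ha  0.008285 cups/person/day
   5 km    700.0 ha  0.009666 cups/person/day
  10 km    900.0 ha  0.012427 cups/person/day
  15 km   1200.0 ha  0.016570 cups/person/day
  20 km   1600.0 ha  0.022093 cups/person/day
```

The bundle places a 600-cell fallow rectangle inside the production-center
county plus 100/200/300/400-cell rectangles inside each successive buffer
annulus (1 ha per cell at 100 m resolution), so the cumulative suitable
areas are exactly 600, 700, 900, 1200 and 1600 ha. At a yield of
10 000 kg/ha, losses of 10/20/30 %, 1 cup/kg and a population of 10⁶, the
no-expansion availability is 600 ha × 10⁴ kg/ha × 0.504 / 10⁶ / 365 ≈
0.008285 cups/person/day — which is what the pipeline recovers.

The same works from the shell:

```
cropsuit make-fixtures --out bundle --seed 1
cropsuit run --config bundle/run_config.yaml
```

which writes `suitable_area_ha.csv`, `cups_per_capita_day.csv` and a JSON
run manifest (including the per-condition filter cascade of every
overlay) under `bundle/results/`.

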