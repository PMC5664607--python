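"""Published national-scale reference values for the seven-crop analysis.

These are the printed results of the national study this package
re-implements: per-crop suitable land area (10^3 ha) and loss-adjusted
per-capita availability (10^-3 cup-eq/person/day) under the five
buffer-expansion scenarios, plus the production-center county shares. The
geospatial inputs behind them (climate normals, soil survey, cropland data
layer, agricultural census) are not redistributable at desk scale, so these
tables serve as fixtures for internal-consistency checks of the reporting
arithmetic and as worked-example inputs — not as ground truth the pipeline
recomputes.
"""

from __future__ import annotations

import pandas as pd

BUFFERS_KM = [0, 5, 10, 15, 20]

CROPS = [
    "dates",
    "kiwis",
    "broccoli",
    "lima_beans",
    "sweet_potatoes",
    "great_northern_beans",
    "mushrooms",
]

MYPLATE_SUBGROUP = {
    "dates": "fruit",
    "kiwis": "fruit",
    "broccoli": "dark green",
    "lima_beans": "starchy",
    "sweet_potatoes": "red and orange",
    "great_northern_beans": "beans and peas",
    "mushrooms": "other",
}

#: production centers: (counties, state, percent of mean national acreage)
PRODUCTION_CENTER_SHARES = {
    "dates": [(("Riverside",), "California", 55)],
    "kiwis": [(("Tulare",), "California", 35),
              (("Butte",), "California", 24)],
    "broccoli": [(("Monterey",), "California", 39),
                 (("Santa Barbara",), "California", 20)],
    "lima_beans": [(("Sussex", "Kent"), "Delaware", 25)],
    "sweet_potatoes": [(("Johnston", "Nash", "Sampson", "Wilson"), "North Carolina", 27),
                       (("Calhoun",), "Mississippi", 12),
                       (("Merced",), "California", 11)],
    "great_northern_beans": [(("Scotts Bluff", "Box Butte", "Morrill"), "Nebraska", 70)],
    "mushrooms": [(("Chester",), "Pennsylvania", 29)],
}

#: cumulative suitable land area by scenario, 10^3 ha (per-crop printed rows)
SUITABLE_AREA_1E3_HA = {
    "dates":                [6.0, 7.3, 8.6, 9.8, 10.3],
    "kiwis":                [10.1, 14.5, 19.4, 24.6, 30.5],
    "broccoli":             [10.7, 12.1, 14.7, 21.1, 27.6],
    "lima_beans":           [3.8, 4.3, 5.1, 6.3, 8.1],
    "sweet_potatoes":       [82.7, 133.9, 188.7, 235.3, 284.5],
    "great_northern_beans": [30.6, 37.1, 43.8, 46.8, 49.7],
    "mushrooms":            [0.1, 0.2, 0.4, 0.8, 1.4],
}

#: printed Total row of the area table, 10^3 ha
SUITABLE_AREA_TOTAL_1E3_HA = [143.9, 209.5, 280.7, 344.7, 412.2]

#: cumulative availability by scenario, 10^-3 cup-eq/person/day
AVAILABILITY_1E3_CUPS = {
    "dates":                [3.4, 4.1, 4.8, 5.5, 5.8],
    "kiwis":                [2.7, 3.8, 5.1, 6.5, 8.0],
    "broccoli":             [6.0, 6.8, 8.2, 11.8, 15.4],
    "lima_beans":           [0.2, 0.2, 0.3, 0.3, 0.4],
    "sweet_potatoes":       [23.0, 37.0, 51.9, 64.6, 78.0],
    "great_northern_beans": [7.2, 8.7, 10.3, 11.0, 11.7],
    "mushrooms":            [1.2, 2.9, 5.6, 10.3, 18.6],
}

#: printed Total row of the availability table, 10^-3 cups/person/day
AVAILABILITY_TOTAL_1E3_CUPS = [43.6, 63.5, 86.3, 110.1, 138.0]

#: currently harvested area, 10^3 ha (national mean 2002-2012)
CURRENT_HARVESTED_1E3_HA = {
    "dates": 3.0, "kiwis": 1.7, "broccoli": 54.1, "lima_beans": 19.2,
    "sweet_potatoes": 43.6, "great_northern_beans": 26.6, "mushrooms": 0.4,
}

#: current availability, 10^-3 cups/person/day (2007-2011 mean); the
#: lima-bean cell prints as "<0.02" and is stored at that bound
CURRENT_AVAILABILITY_1E3_CUPS = {
    "dates": 2.4, "kiwis": 1.6, "broccoli": 42.8, "lima_beans": 0.02,
    "sweet_potatoes": 11.7, "great_northern_beans": 5.9, "mushrooms": 20.6,
}

#: national baseline: total daily per-capita cup-equivalents of all F&V
BASELINE_TOTAL_CUPS_PER_DAY = 2.6

#: suitable land within existing centers, stated in the running text as
#: "nearly 144,000 ha" (upper bound for the no-expansion total)
STATED_NO_EXPANSION_CEILING_1E3_HA = 144.0

#: acreage-share threshold defining a production center
CENTER_SHARE_THRESHOLD = 0.10


def area_frame() -> pd.DataFrame:
    """Per-crop suitable-area rows as a crops x buffers frame (10^3 ha)."""
    return pd.DataFrame.from_dict(SUITABLE_AREA_1E3_HA, orient="index",
                                  columns=BUFFERS_KM).rename_axis("crop_id")


def availability_frame() -> pd.DataFrame:
    """Per-crop availability rows as a crops x buffers frame (10^-3 cups)."""
    return pd.DataFrame.from_dict(AVAILABILITY_1E3_CUPS, orient="index",
                                  columns=BUFFERS_KM).rename_axis("crop_id")


def long_results(frame: pd.DataFrame, value: str) -> pd.DataFrame:
    """Melt a crops x buffers frame into scenario_table's long input form."""
    long = frame.reset_index().melt(id_vars="crop_id", var_name="buffer_km",
                                    value_name=value)
    long["buffer_km"] = long["buffer_km"].astype(float)
    return long
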