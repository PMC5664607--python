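"""Screening a candidate food table down to nutrient-dense, trending crops.

Foods are scored on fiber, calcium, magnesium and potassium per serving,
each expressed as a percent of a daily reference amount; a food is kept when
its score passes a cutoff AND both its domestic consumption and production
series show a strictly positive ordinary-least-squares trend over the most
recent window (five calendar years by default).

The exact published index behind the original screen is not reproducible
from its description, so the aggregator (sum vs mean), the nutrient set, the
reference amounts and the score cutoff are all configurable; the default is
the sum of percent-of-reference contributions over the four nutrients.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ArgumentError, DegenerateSeriesError, ScoringError, SelectionError

DEFAULT_NUTRIENTS = ("fiber_g", "calcium_mg", "magnesium_mg", "potassium_mg")

#: adult daily reference amounts used to normalise nutrient densities
DEFAULT_REFERENCE_INTAKES = {
    "fiber_g": 28.0,
    "calcium_mg": 1300.0,
    "magnesium_mg": 420.0,
    "potassium_mg": 4700.0,
}

MYPLATE_SUBGROUPS = frozenset(
    {"dark green", "starchy", "red and orange", "beans and peas", "other", "fruit"}
)


@dataclass(frozen=True)
class FoodNutrientRecord:
    """Per-serving nutrient content of one candidate food."""

    food_id: str
    name: str
    myplate_subgroup: str
    nutrients: Mapping[str, float]

    def __post_init__(self):
        if self.myplate_subgroup not in MYPLATE_SUBGROUPS:
            raise ArgumentError(
                f"unknown MyPlate subgroup {self.myplate_subgroup!r} for {self.food_id}"
            )
        for k, v in self.nutrients.items():
            if v is not None and v < 0:
                raise ArgumentError(f"negative nutrient amount {k}={v} for {self.food_id}")


@dataclass(frozen=True)
class AnnualSeries:
    """A (year, value) series of annual consumption or production amounts."""

    years: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.years) != len(self.values):
            raise ArgumentError("years and values must have equal length")
        if any(b <= a for a, b in zip(self.years, self.years[1:])):
            raise ArgumentError("years must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ArgumentError("series values must be non-negative")

    def recent(self, window_years: int) -> "AnnualSeries":
        """Restrict to the last ``window_years`` calendar years present."""
        if window_years < 2:
            raise ArgumentError("window must cover at least 2 years")
        return AnnualSeries(self.years[-window_years:], self.values[-window_years:])


class ReferenceIntakes(dict):
    """Per-nutrient daily reference amounts; all strictly positive."""

    def __init__(self, amounts: Mapping[str, float] | None = None):
        super().__init__(amounts if amounts is not None else DEFAULT_REFERENCE_INTAKES)
        for k, v in self.items():
            if not (v > 0):
                raise ArgumentError(f"reference intake for {k} must be positive, got {v}")


def nutrient_density_score(
    record: FoodNutrientRecord,
    refs: ReferenceIntakes | None = None,
    nutrients: Sequence[str] = DEFAULT_NUTRIENTS,
    aggregator: str = "sum",
) -> float:
    """Dimensionless nutrient-density score of one food.

    Default: sum over the four target nutrients of
    ``amount_per_serving / daily_reference * 100``. ``aggregator`` may be
    ``"sum"`` or ``"mean"``. Missing nutrient values raise rather than
    silently contributing zero.
    """
    refs = refs if refs is not None else ReferenceIntakes()
    contributions = []
    for nut in nutrients:
        amount = record.nutrients.get(nut)
        if amount is None:
            raise ScoringError(f"food {record.food_id!r} missing nutrient {nut!r}")
        if nut not in refs:
            raise ScoringError(f"no reference intake for nutrient {nut!r}")
        contributions.append(amount / refs[nut] * 100.0)
    if aggregator == "sum":
        return float(sum(contributions))
    if aggregator == "mean":
        return float(np.mean(contributions))
    raise ArgumentError(f"unknown aggregator {aggregator!r}")


def trend_slope(series: AnnualSeries) -> float:
    """OLS slope of value on year, in value units per year.

    Closed form on centered years: ``sum((x-x̄)(y-ȳ)) / sum((x-x̄)²)``.
    """
    x = np.asarray(series.years, dtype=float)
    y = np.asarray(series.values, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateSeriesError("slope needs >= 2 distinct years")
    dx = x - x.mean()
    return float(np.dot(dx, y - y.mean()) / np.dot(dx, dx))


def select_crops(
    scores: Mapping[str, float],
    consumption: Mapping[str, AnnualSeries],
    production: Mapping[str, AnnualSeries],
    subgroups: Mapping[str, str] | None = None,
    window_years: int = 5,
    score_cutoff: float | None = None,
) -> list[dict]:
    """Keep foods passing the score cutoff with positive consumption AND
    production trends over the most recent ``window_years``.

    ``score_cutoff=None`` uses the top decile of the supplied scores.
    Returns one dict per selected food (``food_id``, ``score``, both slopes,
    and the MyPlate subgroup when ``subgroups`` is given), sorted by
    descending score.
    """
    if not scores:
        return []
    cutoff = (float(np.quantile(list(scores.values()), 0.9))
              if score_cutoff is None else score_cutoff)
    selected = []
    for food_id, score in scores.items():
        if score < cutoff:
            continue
        for name, table in (("consumption", consumption), ("production", production)):
            if food_id not in table:
                raise SelectionError(f"scored food {food_id!r} has no {name} series")
        c_slope = trend_slope(consumption[food_id].recent(window_years))
        p_slope = trend_slope(production[food_id].recent(window_years))
        if c_slope > 0 and p_slope > 0:
            row = {"food_id": food_id, "score": score,
                   "consumption_slope": c_slope, "production_slope": p_slope}
            if subgroups is not None:
                row["myplate_subgroup"] = subgroups[food_id]
            selected.append(row)
    return sorted(selected, key=lambda r: -r["score"])
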