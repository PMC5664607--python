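"""From suitable land area to loss-adjusted per-capita cup-equivalents.

The conversion chain is linear and multiplicative:

    area (ha) x yield (kg/ha)                       -> farm-weight mass (kg/yr)
    x (1-farm_loss)(1-retail_loss)(1-consumer_loss) -> consumer-weight mass
    x cups_per_kg / population / 365                -> cup-eq / person / day

Supply-chain losses follow the loss-adjusted food availability accounting
structure, collapsed here into three fractional stages plus one mass-to-cup
conversion factor per crop; the factors themselves are inputs. Per-crop
results are reported cumulatively across buffer scenarios (the nesting of
scenario masks makes cumulative reporting automatic), and tables carry a
Total row summed at full precision, rounding only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, ConfigurationError, ReportError

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class YieldRecord:
    """State-level farm-weight yield for one crop (kg per hectare)."""

    crop_id: str
    state: str
    yield_kg_per_ha: float

    def __post_init__(self):
        if not (self.yield_kg_per_ha > 0):
            raise ConfigurationError(
                f"yield for {self.crop_id}/{self.state} must be positive")


@dataclass(frozen=True)
class LossChain:
    """Farm/retail/consumer loss fractions and cup conversion for one crop."""

    crop_id: str
    farm_loss: float
    retail_loss: float
    consumer_loss: float
    cups_per_kg: float

    def __post_init__(self):
        for name in ("farm_loss", "retail_loss", "consumer_loss"):
            f = getattr(self, name)
            if not (0 <= f < 1):
                raise ConfigurationError(
                    f"{name} for {self.crop_id} must be in [0, 1), got {f}")
        if not (self.cups_per_kg > 0):
            raise ConfigurationError(f"cups_per_kg for {self.crop_id} must be positive")


@dataclass
class ScenarioResult:
    """Suitable area and derived availability for one crop x buffer."""

    crop_id: str
    buffer_km: float
    suitable_area_ha: float
    production_kg_farm: float
    cups_per_capita_day: float

    def __post_init__(self):
        for name in ("suitable_area_ha", "production_kg_farm", "cups_per_capita_day"):
            if getattr(self, name) < 0:
                raise ArgumentError(f"{name} must be non-negative")


def production_from_area(area_ha: float, yield_record: YieldRecord) -> float:
    """Farm-weight production (kg/yr) from suitable area; linear in both."""
    if area_ha < 0:
        raise ArgumentError(f"area must be >= 0 ha, got {area_ha}")
    return area_ha * yield_record.yield_kg_per_ha


def loss_adjust(mass_kg: float, chain: LossChain) -> float:
    """Consumer-available mass after farm, retail and consumer losses."""
    if mass_kg < 0:
        raise ArgumentError(f"mass must be >= 0 kg, got {mass_kg}")
    return (mass_kg * (1 - chain.farm_loss) * (1 - chain.retail_loss)
            * (1 - chain.consumer_loss))


def per_capita_cups(consumer_kg_per_year: float, chain: LossChain,
                    population: float) -> float:
    """Cup-equivalents per person per day from annual consumer-weight mass."""
    if not (population > 0):
        raise ArgumentError(f"population must be positive, got {population}")
    if consumer_kg_per_year < 0:
        raise ArgumentError("consumer mass must be >= 0 kg")
    return consumer_kg_per_year * chain.cups_per_kg / population / DAYS_PER_YEAR


def availability_chain(area_ha: float, yield_record: YieldRecord,
                       chain: LossChain, population: float) -> ScenarioResult:
    """Full area -> cups chain for one crop in one scenario (helper)."""
    farm_kg = production_from_area(area_ha, yield_record)
    consumer_kg = loss_adjust(farm_kg, chain)
    cups = per_capita_cups(consumer_kg, chain, population)
    return ScenarioResult(
        crop_id=yield_record.crop_id, buffer_km=float("nan"),
        suitable_area_ha=area_ha, production_kg_farm=farm_kg,
        cups_per_capita_day=cups)


def scenario_table(results: Sequence[ScenarioResult] | pd.DataFrame,
                   value: str = "cups_per_capita_day",
                   crop_order: Sequence[str] | None = None) -> pd.DataFrame:
    """Report table: one row per crop, one column per buffer, plus Total.

    Every crop must supply every buffer that any crop supplies. The Total
    row is the exact column-wise sum of the crop rows (full precision);
    values stay cumulative in buffer because the underlying scenario masks
    nest. Rounding is left to presentation (see :func:`format_report`).
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        df = pd.DataFrame([vars(r) for r in results])
    if df.empty:
        raise ReportError("no scenario results to tabulate")
    table = df.pivot_table(index="crop_id", columns="buffer_km", values=value,
                           aggfunc="sum")
    if table.isna().any().any():
        missing = [(c, b) for (c, b) in zip(*np.where(table.isna().values))]
        raise ReportError(f"missing crop x buffer cells in report: {missing}")
    if crop_order is not None:
        table = table.reindex(crop_order)
        if table.isna().any().any():
            raise ReportError("crop_order names crops absent from results")
    total = table.sum(axis=0)
    table.loc["Total"] = total
    # Total first, matching the published table layout
    return table.reindex(["Total"] + [c for c in table.index if c != "Total"])


def percent_increase(added: float, baseline: float) -> float:
    """Percent increase of ``added`` over ``baseline`` (same units)."""
    if not (baseline > 0):
        raise ArgumentError(f"baseline must be positive, got {baseline}")
    if added < 0:
        raise ArgumentError("added amount must be >= 0")
    return added / baseline * 100.0


def omit_crop_sensitivity(table: pd.DataFrame, crop_id: str) -> pd.Series:
    """Percent reduction of the Total row when one crop is omitted.

    Expects a :func:`scenario_table`-shaped frame (Total row present).
    Returns the per-column reduction in percent: crop value / Total x 100.
    """
    if crop_id not in table.index:
        raise ArgumentError(f"crop {crop_id!r} not in table")
    if "Total" not in table.index:
        raise ArgumentError("table lacks a Total row; build it with scenario_table")
    total = table.loc["Total"]
    if (total <= 0).any():
        raise ArgumentError("Total row must be positive in every scenario column")
    return table.loc[crop_id] / total * 100.0


def format_report(table: pd.DataFrame, decimals: int = 1,
                  scale: float = 1.0) -> pd.DataFrame:
    """Presentation rounding: divide by ``scale`` then round.

    The published tables print areas in 10^3 ha (``scale=1e3``) and
    availability in 10^-3 cup-eq/person/day (``scale=1e-3``), both to one
    decimal.
    """
    return (table / scale).round(decimals)
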