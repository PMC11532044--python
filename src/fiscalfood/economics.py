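"""Societal cost ledger and incremental cost-effectiveness ratio.

Sign convention: costs are positive, savings negative.  The ledger has four
entries — household food spending, water, carbon and healthcare — all in
billion 2020 Rials (BR) per year for the reference population; the ICER is
the signed total divided by DALYs averted and is compared with a
willingness-to-pay threshold of one GDP per capita per DALY (0.61 BR by
default).

Household cost values the changed basket at pre-tax prices: the tax payment
itself is a transfer from households to government and cancels out of the
societal ledger.  The alternative bookkeeping (consumer prices with revenue
credited back) is available via ``use_posttax_prices`` and is equivalent up
to the transfer.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .errors import DomainError, MissingCoefficientError, StructuralError
from .types import CostCoefficients, FoodGroupProfile, WATER_PRICE_VARIANTS
from .environment import FootprintResult

__all__ = [
    "DEFAULT_POPULATION_SCALE",
    "household_cost",
    "environmental_cost",
    "healthcare_cost",
    "CostLedger",
    "assemble_ledger",
    "ICERResult",
    "icer",
]

#: AME-days per year for the reference 1-million-person population.  The
#: per-AME basket is treated as the per-person basket of 1e6 adults over 365
#: days; the factor is exposed so either reading of the scaling can be used.
DEFAULT_POPULATION_SCALE = 1_000_000 * 365.0

_BR = 1e9  # Rials per billion Rials


def household_cost(
    baseline_basket: Sequence[FoodGroupProfile],
    counterfactual_basket: Sequence[FoodGroupProfile],
    population_scale: float = DEFAULT_POPULATION_SCALE,
    use_posttax_prices: bool = False,
) -> float:
    """Change in household food spending, billion Rials per year.

    Valued at the baseline (pre-tax) prices unless ``use_posttax_prices``;
    quantities are purchased g/day per AME.  A net quantity decrease yields
    a negative entry (saving).
    """
    base = {p.name: p for p in baseline_basket}
    cf = {p.name: p for p in counterfactual_basket}
    if set(base) != set(cf):
        raise StructuralError("baskets cover different groups")
    delta_rials_per_day = 0.0
    for name, b in base.items():
        c = cf[name]
        price = c.price if use_posttax_prices else b.price
        delta_rials_per_day += price * (c.quantity - b.quantity) / 1000.0
    return delta_rials_per_day * population_scale / _BR


def environmental_cost(
    footprint_result: FootprintResult,
    coefficients: CostCoefficients,
    water_variant: str = "agricultural",
    population_scale: float = DEFAULT_POPULATION_SCALE,
) -> tuple[float, float]:
    """(water, carbon) cost deltas in billion Rials per year.

    Water volume changes are priced per m3 under the chosen variant
    (agricultural, accounting or industrial); carbon mass changes at the
    social cost of carbon.  Footprint reductions come out negative.
    """
    if water_variant not in WATER_PRICE_VARIANTS:
        raise MissingCoefficientError(f"unknown water price variant {water_variant!r}")
    try:
        water_price = coefficients.water_price[water_variant]
    except KeyError as exc:
        raise MissingCoefficientError(f"no water price for variant {water_variant!r}") from exc
    water = footprint_result.water_delta / 1000.0 * water_price * population_scale / _BR
    carbon = footprint_result.carbon_delta * coefficients.scc * population_scale / _BR
    return water, carbon


def healthcare_cost(
    averted_cases: Mapping[str, float],
    treatment_cost: Mapping[str, float],
    cpi_factor: float | Mapping[str, float] = 1.0,
) -> float:
    """Healthcare cost delta: averted cases save their treatment cost.

    Returns -sum_d cases_d x cost_d x cpi_d / 1e9 (billion Rials); negative
    when cases are averted.
    """
    total = 0.0
    for disease, cases in averted_cases.items():
        try:
            cost = treatment_cost[disease]
        except KeyError as exc:
            raise MissingCoefficientError(f"no treatment cost for disease {disease!r}") from exc
        if cost < 0:
            raise DomainError("treatment costs must be >= 0")
        cpi = cpi_factor.get(disease, 1.0) if isinstance(cpi_factor, Mapping) else cpi_factor
        total -= cases * cost * cpi
    return total / _BR


@dataclass(frozen=True)
class CostLedger:
    """Four-entry societal cost ledger, billion Rials per year."""

    scenario: str
    household: float
    water: float
    carbon: float
    healthcare: float

    @property
    def total(self) -> float:
        return self.household + self.water + self.carbon + self.healthcare


def assemble_ledger(
    household: float,
    water: float,
    carbon: float,
    healthcare: float,
    scenario: str = "",
) -> CostLedger:
    """Bundle the four cost entries; the total is their exact sum."""
    return CostLedger(scenario, household, water, carbon, healthcare)


@dataclass(frozen=True)
class ICERResult:
    scenario: str
    icer: float  # billion Rials per DALY averted
    dalys_averted: float
    cost_effective: bool
    dominated: bool = False


def icer(
    ledger: CostLedger,
    dalys_averted: float,
    threshold: float = 0.61,
) -> ICERResult:
    """Incremental cost-effectiveness ratio of one scenario vs no tax.

    ``threshold`` is in billion Rials per DALY.  A scenario that costs more
    while losing health (negative DALYs averted at positive cost) is flagged
    dominated and is never cost-effective.
    """
    if dalys_averted == 0:
        raise DomainError("ICER undefined: zero DALYs averted")
    value = ledger.total / dalys_averted
    if dalys_averted < 0 and ledger.total > 0:
        return ICERResult(ledger.scenario, value, dalys_averted, False, dominated=True)
    return ICERResult(ledger.scenario, value, dalys_averted, value <= threshold)
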