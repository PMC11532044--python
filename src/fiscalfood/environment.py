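"""Water and carbon footprints of the food basket.

Footprints are computed on purchased (pre-waste) quantities: the footprint
coefficients describe production-side burdens, which include food that is
later wasted.  Water is litres per kg, carbon kg CO2-equivalent per kg; the
single water coefficient collapses green/blue/grey components.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

from .errors import DomainError, MissingCoefficientError, StructuralError
from .types import FoodGroupProfile

__all__ = ["basket_footprint", "footprint_change", "FootprintResult"]


def _profile_map(profiles) -> Mapping[str, FoodGroupProfile]:
    return profiles if isinstance(profiles, Mapping) else {p.name: p for p in profiles}


def basket_footprint(
    intakes: Mapping[str, float],
    profiles: Sequence[FoodGroupProfile] | Mapping[str, FoodGroupProfile],
) -> tuple[float, float]:
    """(water L/day, carbon kg CO2e/day) of a basket of g/day quantities."""
    pmap = _profile_map(profiles)
    water = carbon = 0.0
    for group, grams in intakes.items():
        try:
            p = pmap[group]
        except KeyError as exc:
            raise MissingCoefficientError(f"no footprint coefficients for group {group!r}") from exc
        kg = grams / 1000.0
        water += kg * p.water_footprint
        carbon += kg * p.carbon_footprint
    return water, carbon


@dataclass(frozen=True)
class FootprintResult:
    """Baseline vs counterfactual footprints of one scenario, per AME-day."""

    scenario: str
    water_baseline: float  # L/day per AME
    water_counterfactual: float
    carbon_baseline: float  # kg CO2e/day per AME
    carbon_counterfactual: float

    @property
    def water_pct_change(self) -> float:
        return 100.0 * (self.water_counterfactual - self.water_baseline) / self.water_baseline

    @property
    def carbon_pct_change(self) -> float:
        return 100.0 * (self.carbon_counterfactual - self.carbon_baseline) / self.carbon_baseline

    @property
    def water_delta(self) -> float:
        """L/day per AME; negative when the tax saves water."""
        return self.water_counterfactual - self.water_baseline

    @property
    def carbon_delta(self) -> float:
        """kg CO2e/day per AME."""
        return self.carbon_counterfactual - self.carbon_baseline


def footprint_change(
    baseline_basket: Mapping[str, float],
    counterfactual_basket: Mapping[str, float],
    profiles: Sequence[FoodGroupProfile] | Mapping[str, FoodGroupProfile],
    scenario: str = "",
) -> FootprintResult:
    """Footprint shift between two baskets of purchased g/day quantities."""
    if set(baseline_basket) != set(counterfactual_basket):
        raise StructuralError("baseline and counterfactual baskets cover different groups")
    wb, cb = basket_footprint(baseline_basket, profiles)
    wc, cc = basket_footprint(counterfactual_basket, profiles)
    if wb == 0 or cb == 0:
        raise DomainError("baseline footprint is zero; percent change undefined")
    return FootprintResult(scenario, wb, wc, cb, cc)
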