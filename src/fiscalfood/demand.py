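"""Demand response of the household food basket to an ad-valorem tax.

The response rule is the first-order point-elasticity approximation

    dQ_i / Q_i = sum_j e[i, j] * dP_j / P_j

where ``dP_j / P_j = pass_through * rate_j`` is the consumer price change of
group *j*.  A multiplicative ("loglog") variant,
``Q*/Q = prod_j (1 + dP_j/P_j) ** e[i, j]``, is available for sensitivity
exploration; the linear rule is the default and is what the calibration
back-solve assumes.

Waste adjustment and adult-male-equivalent (AME) scaling convert purchased
household quantities into consumed g/day per adult-equivalent.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

from .errors import DomainError, MissingCoefficientError, StructuralError
from .types import ElasticityMatrix, FoodGroupProfile, HouseholdRecord, Member, TaxScenario

logger = logging.getLogger(__name__)

__all__ = [
    "price_change",
    "apply_tax_scenario",
    "adjust_for_waste",
    "AmeCoefficientTable",
    "default_ame_table",
    "ame_units",
    "per_ame_intake",
]


def price_change(scenario: TaxScenario, group: str, groups: Iterable[str] | None = None) -> float:
    """Relative consumer price change for ``group``: pass_through x rate.

    ``groups``, when given, is the basket the scenario is applied to; a group
    outside it raises :class:`MissingCoefficientError`.  Untaxed groups
    return 0.
    """
    if groups is not None and group not in set(groups):
        raise MissingCoefficientError(f"group {group!r} not in basket")
    return scenario.pass_through * float(scenario.rates.get(group, 0.0))


def apply_tax_scenario(
    basket: Sequence[FoodGroupProfile],
    elasticities: ElasticityMatrix,
    scenario: TaxScenario,
    response: str = "linear",
) -> list[FoodGroupProfile]:
    """Apply a tax scenario to a basket and return the counterfactual basket.

    The returned profiles carry updated (post-response) purchased quantities
    and post-tax consumer prices; every coefficient field is unchanged.
    Quantities are floored at zero — a warning is logged when the floor
    binds, because flooring breaks the linearity of the response.
    """
    names = [p.name for p in basket]
    if set(names) != set(elasticities.groups):
        raise StructuralError("basket groups do not match elasticity matrix groups")
    unknown = set(scenario.rates) - set(names)
    if unknown:
        raise MissingCoefficientError(f"scenario taxes unknown groups {sorted(unknown)}")

    e = elasticities.reordered(names).e
    dp = np.array([price_change(scenario, g) for g in names])
    if response == "linear":
        rel = e @ dp
    elif response == "loglog":
        rel = np.expm1(e @ np.log1p(dp))
    else:
        raise DomainError(f"unknown response rule {response!r}")

    out: list[FoodGroupProfile] = []
    for profile, r, d in zip(basket, rel, dp):
        q = profile.quantity * (1.0 + r)
        if q < 0:
            logger.warning(
                "quantity of %s floored at 0 (response %.3f); linearity broken",
                profile.name, r,
            )
            q = 0.0
        out.append(replace(profile, quantity=q, price=profile.price * (1.0 + d)))
    return out


def adjust_for_waste(quantity_purchased: float, waste_fraction: float) -> float:
    """Convert a purchased quantity to the quantity actually consumed."""
    if not 0.0 <= waste_fraction < 1.0:
        raise DomainError("waste_fraction must lie in [0, 1)")
    if quantity_purchased < 0:
        raise DomainError("quantity_purchased must be >= 0")
    return quantity_purchased * (1.0 - waste_fraction)


@dataclass(frozen=True)
class _AmeBand:
    age_lo: float
    age_hi: float
    male: float
    female: float


class AmeCoefficientTable:
    """Adult-male-equivalent coefficients by age band and sex.

    The reference individual — a moderately active male aged 18-30 — has
    coefficient exactly 1.0; every other member's coefficient expresses their
    energy needs relative to him.
    """

    def __init__(self, bands: Sequence[_AmeBand]):
        self._bands = tuple(sorted(bands, key=lambda b: b.age_lo))

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, float]]) -> "AmeCoefficientTable":
        return cls([
            _AmeBand(float(r["age_lo"]), float(r["age_hi"]), float(r["male"]), float(r["female"]))
            for r in rows
        ])

    def coefficient(self, age: float, sex: str) -> float:
        if sex not in ("male", "female"):
            raise MissingCoefficientError(f"unknown sex {sex!r}")
        for band in self._bands:
            if band.age_lo <= age <= band.age_hi:
                return band.male if sex == "male" else band.female
        raise MissingCoefficientError(f"no AME coefficient for age {age}")


def default_ame_table() -> AmeCoefficientTable:
    """Packaged default AME coefficients (synthetic values; see data file)."""
    path = resources.files("fiscalfood.data") / "ame_coefficients_synthetic.csv"
    with path.open("r", encoding="utf-8") as fh:
        return AmeCoefficientTable.from_rows(csv.DictReader(fh))


def ame_units(
    members: Sequence[Member | tuple[float, str]],
    coefficient_table: AmeCoefficientTable,
) -> float:
    """Total AME units of a household: the sum of member coefficients."""
    total = 0.0
    for m in members:
        age, sex = (m.age, m.sex) if isinstance(m, Member) else m
        total += coefficient_table.coefficient(age, sex)
    return total


def per_ame_intake(
    record: HouseholdRecord,
    coefficient_table: AmeCoefficientTable,
    waste_fractions: Mapping[str, float],
) -> dict[str, float]:
    """Waste-adjusted consumed quantity per AME unit, per food group."""
    units = ame_units(record.members, coefficient_table)
    if units <= 0:
        raise DomainError(f"household {record.id!r} has zero AME units")
    out: dict[str, float] = {}
    for group, quantity in record.quantities.items():
        try:
            waste = waste_fractions[group]
        except KeyError as exc:
            raise MissingCoefficientError(f"no waste fraction for group {group!r}") from exc
        out[group] = adjust_for_waste(quantity, waste) / units
    return out
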