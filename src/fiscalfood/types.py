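"""Core domain types shared across the pipeline.

Units are fixed package-wide:

* quantities — grams per day per adult-male-equivalent (AME) unless stated;
* prices — 2020 Iranian Rials per kilogram;
* energy — kilojoules per 100 g of food, kilojoules per day for intakes;
* footprints — litres of freshwater per kg and kg CO2-equivalent per kg;
* monetary aggregates — billion Rials (BR) per year for a fixed reference
  population.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, MissingCoefficientError, StructuralError

#: canonical labels for the three taxed food groups
SAS = "sugar_and_sweets"
SSB = "ssb"
HOAF = "hydrogenated_oil_and_animal_fats"
TAXED_GROUPS: tuple[str, ...] = (SAS, SSB, HOAF)

#: nutritional risk factors tracked by the exposure stage
RISK_FACTORS: tuple[str, ...] = ("sugar", "ssb", "sfa", "tfa", "bmi")

#: the six diet-related diseases whose burden is modelled
DISEASES: tuple[str, ...] = (
    "ischemic_heart_disease",
    "ischemic_stroke",
    "type_2_diabetes",
    "osteoarthritis",
    "colorectal_cancer",
    "stomach_cancer",
)

SEXES: tuple[str, str] = ("male", "female")


@dataclass(frozen=True)
class FoodGroupProfile:
    """One food group: quantity, price and every per-kg coefficient downstream
    stages need (nutrient composition, waste, water/carbon footprints)."""

    name: str
    price: float  # Rials per kg, pre-tax consumer price
    quantity: float  # g/day per AME, as purchased
    waste_fraction: float = 0.0  # fraction lost between purchase and intake
    energy_density: float = 0.0  # kJ per 100 g
    sugar_content: float = 0.0  # g per 100 g
    sfa_content: float = 0.0  # g per 100 g
    tfa_content: float = 0.0  # g per 100 g
    water_footprint: float = 0.0  # L per kg
    carbon_footprint: float = 0.0  # kg CO2e per kg

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ConfigurationError(f"price must be > 0 for group {self.name!r}")
        if self.quantity < 0:
            raise ConfigurationError(f"quantity must be >= 0 for group {self.name!r}")
        if not 0.0 <= self.waste_fraction < 1.0:
            raise ConfigurationError(
                f"waste_fraction must lie in [0, 1) for group {self.name!r}"
            )
        for fld in ("energy_density", "sugar_content", "sfa_content", "tfa_content",
                    "water_footprint", "carbon_footprint"):
            if getattr(self, fld) < 0:
                raise ConfigurationError(f"{fld} must be >= 0 for group {self.name!r}")

    @property
    def consumed_quantity(self) -> float:
        """Waste-adjusted intake, g/day per AME."""
        return self.quantity * (1.0 - self.waste_fraction)

    def with_quantity(self, quantity: float) -> "FoodGroupProfile":
        return replace(self, quantity=quantity)


class ElasticityMatrix:
    """Square matrix of own/cross price elasticities.

    ``e[i, j]`` is the percent change in the quantity of group *i* per 1%
    change in the price of group *j*.  The diagonal (own-price elasticities)
    must be strictly negative.
    """

    def __init__(self, groups: Sequence[str], e: np.ndarray | Sequence[Sequence[float]]):
        e = np.asarray(e, dtype=float)
        groups = tuple(groups)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise StructuralError("elasticity matrix must be square")
        if e.shape[0] != len(groups):
            raise StructuralError("elasticity matrix size must match group labels")
        if len(set(groups)) != len(groups):
            raise StructuralError("elasticity group labels must be unique")
        if not np.all(np.diag(e) < 0):
            raise ConfigurationError("own-price elasticities (diagonal) must be strictly negative")
        self.groups = groups
        self.e = e
        self._index = {g: i for i, g in enumerate(groups)}

    def __getitem__(self, key: tuple[str, str]) -> float:
        gi, gj = key
        try:
            return float(self.e[self._index[gi], self._index[gj]])
        except KeyError as exc:
            raise MissingCoefficientError(f"unknown food group {exc.args[0]!r}") from exc

    def own(self, group: str) -> float:
        return self[group, group]

    def reordered(self, groups: Sequence[str]) -> "ElasticityMatrix":
        """Return a copy whose rows/columns follow ``groups``."""
        idx = [self._index[g] for g in groups]
        return ElasticityMatrix(groups, self.e[np.ix_(idx, idx)])

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ElasticityMatrix)
            and self.groups == other.groups
            and np.array_equal(self.e, other.e)
        )

    def __repr__(self) -> str:
        return f"ElasticityMatrix(groups={self.groups!r}, e={self.e!r})"


@dataclass(frozen=True)
class TaxScenario:
    """An ad-valorem tax scenario: per-group rates plus a pass-through."""

    name: str
    rates: Mapping[str, float]
    pass_through: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pass_through <= 1.0:
            raise ConfigurationError("pass_through must lie in [0, 1]")
        for group, rate in self.rates.items():
            if rate < 0:
                raise ConfigurationError(f"tax rate for group {group!r} must be >= 0")

    def with_uniform_rate(self, rate: float) -> "TaxScenario":
        """Same taxed groups, all at ``rate`` (used by sensitivity scenarios)."""
        return TaxScenario(
            name=f"{self.name}@{rate:g}",
            rates={g: rate for g in self.rates},
            pass_through=self.pass_through,
        )


@dataclass(frozen=True)
class Member:
    age: float  # years
    sex: str  # "male" | "female"


@dataclass(frozen=True)
class HouseholdRecord:
    """One surveyed household: roster plus purchased quantities (g/day,
    household total)."""

    id: str
    members: tuple[Member, ...]
    quantities: Mapping[str, float]

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError(f"household {self.id!r} must have at least one member")
        for g, q in self.quantities.items():
            if q < 0:
                raise ConfigurationError(f"household {self.id!r}: quantity for {g!r} must be >= 0")


@dataclass(frozen=True)
class RelativeRisk:
    """Relative risk of ``disease`` per ``increment`` units of ``risk_factor``
    exposure, with log-normal uncertainty of scale ``log_sd``."""

    risk_factor: str
    disease: str
    rr_per_increment: float  # dimensionless, > 0
    increment: float  # exposure units (g/day, or kg/m2 for BMI)
    log_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_per_increment <= 0:
            raise ConfigurationError("rr_per_increment must be > 0")
        if self.increment <= 0:
            raise ConfigurationError("increment must be > 0")
        if self.log_sd < 0:
            raise ConfigurationError("log_sd must be >= 0")


@dataclass
class Stratum:
    """One age-band x sex cell: population count, per-disease incidence and
    DALY rates (per 100,000 person-years), and anthropometry moments used to
    simulate individuals."""

    age_band: str  # "25-29", ..., "80+"
    sex: str
    population: float
    incidence: dict[str, float] = field(default_factory=dict)
    daly: dict[str, float] = field(default_factory=dict)
    height_mean: float = 1.68  # m
    height_sd: float = 0.07
    weight_mean: float = 72.0  # kg
    weight_sd: float = 12.0

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ConfigurationError("stratum population must be >= 0")
        for rates in (self.incidence, self.daly):
            for d, r in rates.items():
                if r < 0:
                    raise ConfigurationError(f"rate for {d!r} must be >= 0")

    @property
    def key(self) -> tuple[str, str]:
        return (self.age_band, self.sex)


WATER_PRICE_VARIANTS: tuple[str, ...] = ("agricultural", "accounting", "industrial")


@dataclass
class CostCoefficients:
    """Monetary coefficients for the societal cost ledger (2020 Rials)."""

    water_price: dict[str, float]  # Rials per m3, keyed by variant
    scc: float  # social cost of carbon, Rials per kg CO2e
    treatment_cost: dict[str, float]  # Rials per incident case, per disease
    cpi_factor: float | dict[str, float] = 1.0  # inflator to 2020 Rials
    threshold_br: float = 0.61  # cost-effectiveness threshold, BR per DALY

    def __post_init__(self) -> None:
        for variant, price in self.water_price.items():
            if variant not in WATER_PRICE_VARIANTS:
                raise ConfigurationError(f"unknown water price variant {variant!r}")
            if price < 0:
                raise ConfigurationError("water_price must be >= 0")
        if self.scc < 0:
            raise ConfigurationError("scc must be >= 0")
        for d, c in self.treatment_cost.items():
            if c < 0:
                raise ConfigurationError(f"treatment_cost for {d!r} must be >= 0")
        if self.threshold_br <= 0:
            raise ConfigurationError("threshold_br must be > 0")

    def cpi(self, disease: str) -> float:
        if isinstance(self.cpi_factor, Mapping):
            return float(self.cpi_factor.get(disease, 1.0))
        return float(self.cpi_factor)


@dataclass
class InputBundle:
    """Everything one scenario run consumes, bundled and cross-validated."""

    profiles: tuple[FoodGroupProfile, ...]
    households: tuple[HouseholdRecord, ...]
    elasticities: ElasticityMatrix
    rr_table: tuple[RelativeRisk, ...]
    strata: tuple[Stratum, ...]
    costs: CostCoefficients
    population_size: int = 1_000_000
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate food group profile names")
        known = set(names)
        if set(self.elasticities.groups) != known:
            raise StructuralError("elasticity groups do not match food group profiles")
        for hh in self.households:
            unknown = set(hh.quantities) - known
            if unknown:
                raise StructuralError(
                    f"household {hh.id!r} references unknown groups {sorted(unknown)}"
                )
        total = sum(s.population for s in self.strata)
        if self.strata and abs(total - self.population_size) > 0.5:
            raise StructuralError(
                f"stratum populations sum to {total:.0f}, expected {self.population_size}"
            )

    @property
    def profile_map(self) -> dict[str, FoodGroupProfile]:
        return {p.name: p for p in self.profiles}

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)

    @property
    def waste_fractions(self) -> dict[str, float]:
        return {p.name: p.waste_fraction for p in self.profiles}
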