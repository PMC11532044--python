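"""Synthetic model inputs with the statistical structure the analysis assumes.

Two entry points:

* :func:`generate_bundle` draws a full input bundle (households,
  elasticities, relative risks, strata, coefficient tables) from a seeded
  configuration — right-skewed positive purchase quantities, strictly
  negative own-price elasticities with dominated cross terms, harmful RRs
  with log-normal uncertainty, and age-graded disease rates.

* :func:`calibration_bundle` returns a fixed bundle whose elasticities are
  back-solved under the linear demand rule so that the three reference tax
  scenarios (25% sugar-and-sweets, 30% SSB, 30% hydrogenated-oil-and-
  animal-fats) reproduce stated own-group exposure responses exactly
  (-10.76% sugar, -14.26% SSB, -7.82% SFA).  To keep the back-solve exact
  each marker nutrient lives in a single food group (sugar only in the SAS
  group, SFA/TFA only in the HOAF group); the substitution cross terms are
  chosen to reproduce the observed signs (an SSB tax raising red meat,
  fruit, vegetable and legume purchases).

All values here are synthetic stand-ins for survey microdata, burden-of-
disease rates and prior demand-system estimates; they are plausible in
magnitude but are not the real inputs.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .demand import default_ame_table, ame_units
from .errors import ConfigurationError
from .types import (
    DISEASES,
    HOAF,
    SAS,
    SSB,
    TAXED_GROUPS,
    CostCoefficients,
    ElasticityMatrix,
    FoodGroupProfile,
    HouseholdRecord,
    InputBundle,
    Member,
    RelativeRisk,
    Stratum,
)

__all__ = [
    "GeneratorConfig",
    "generate_bundle",
    "calibration_bundle",
    "AGE_BANDS",
    "DEFAULT_FOOD_GROUPS",
]

#: 5-year age bands, 25 through 80+
AGE_BANDS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)

#: declining-with-age population weights, one per band (sum to 1)
_AGE_PROFILE = (0.13, 0.125, 0.12, 0.11, 0.10, 0.09,
                0.08, 0.07, 0.06, 0.05, 0.035, 0.03)

DEFAULT_FOOD_GROUPS: tuple[str, ...] = (
    SAS, SSB, HOAF,
    "red_meat", "fruits", "vegetables", "legumes", "bread_and_cereals",
)

#: per-group defaults: (price R/kg, mean quantity g/day/AME, waste, energy
#: kJ/100g, sugar, sfa, tfa g/100g, water L/kg, carbon kgCO2e/kg)
_GROUP_DEFAULTS: dict[str, tuple] = {
    SAS: (400_000, 80.0, 0.05, 1600.0, 70.0, 0.0, 0.0, 1800.0, 3.0),
    SSB: (150_000, 100.0, 0.02, 180.0, 0.0, 0.0, 0.0, 300.0, 0.5),
    HOAF: (500_000, 40.0, 0.03, 3500.0, 0.0, 45.0, 12.0, 5500.0, 8.0),
    "red_meat": (1_300_000, 50.0, 0.08, 1000.0, 0.0, 0.0, 0.0, 15_400.0, 27.0),
    "fruits": (200_000, 200.0, 0.15, 250.0, 0.0, 0.0, 0.0, 960.0, 1.1),
    "vegetables": (100_000, 250.0, 0.15, 100.0, 0.0, 0.0, 0.0, 320.0, 2.0),
    "legumes": (350_000, 30.0, 0.05, 1400.0, 0.0, 0.0, 0.0, 4000.0, 2.0),
    "bread_and_cereals": (60_000, 320.0, 0.10, 1100.0, 0.0, 0.0, 0.0, 1600.0, 1.4),
}


def _default_mean_quantities(names: Sequence[str]) -> dict[str, float]:
    return {g: (_GROUP_DEFAULTS[g][1] if g in _GROUP_DEFAULTS else 100.0) for g in names}


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic input generator.

    A single seed drives all sub-generators in a fixed order, so a given
    config always yields a bit-identical bundle.
    """

    seed: int = 0
    n_households: int = 1000
    n_food_groups: int = len(DEFAULT_FOOD_GROUPS)
    food_group_names: tuple[str, ...] = DEFAULT_FOOD_GROUPS
    mean_quantity: Mapping[str, float] | None = None  # g/day per AME
    quantity_dispersion: float = 0.6  # coefficient of variation (log-normal)
    own_elasticity_range: tuple[float, float] = (-0.9, -0.2)
    cross_elasticity_scale: float = 0.04
    rr_log_sd_scale: float = 0.05
    population_size: int = 1_000_000

    def __post_init__(self) -> None:
        self.food_group_names = tuple(self.food_group_names)
        if self.n_food_groups != len(self.food_group_names):
            raise ConfigurationError(
                "n_food_groups does not match the length of food_group_names"
            )
        if self.n_food_groups < 3:
            raise ConfigurationError("n_food_groups must be >= 3")
        missing = set(TAXED_GROUPS) - set(self.food_group_names)
        if missing:
            raise ConfigurationError(
                f"food_group_names must include the taxed groups; missing {sorted(missing)}"
            )
        lo, hi = self.own_elasticity_range
        if not (lo <= hi < 0):
            raise ConfigurationError("own_elasticity_range must lie strictly below 0")
        if self.mean_quantity is None:
            self.mean_quantity = _default_mean_quantities(self.food_group_names)
        else:
            self.mean_quantity = dict(self.mean_quantity)
            missing_q = set(self.food_group_names) - set(self.mean_quantity)
            if missing_q:
                raise ConfigurationError(f"mean_quantity missing groups {sorted(missing_q)}")
        if any(q <= 0 for q in self.mean_quantity.values()):
            raise ConfigurationError("mean_quantity values must all be > 0")
        if self.quantity_dispersion < 0:
            raise ConfigurationError("quantity_dispersion must be >= 0")
        if self.cross_elasticity_scale < 0:
            raise ConfigurationError("cross_elasticity_scale must be >= 0")
        if self.rr_log_sd_scale < 0:
            raise ConfigurationError("rr_log_sd_scale must be >= 0")
        if self.n_households < 1:
            raise ConfigurationError("n_households must be >= 1")
        if self.population_size < 1:
            raise ConfigurationError("population_size must be >= 1")


# --- strata -----------------------------------------------------------------

#: anthropometry by sex: (height mean m, height sd, weight mean kg, weight sd)
_ANTHRO = {"male": (1.70, 0.07, 75.0, 12.0), "female": (1.58, 0.06, 69.0, 13.0)}

#: per-disease (base incidence per 100k at 25-29, age gradient per band,
#: male multiplier, DALYs per incident case)
_DISEASE_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "ischemic_heart_disease": (80.0, 1.28, 1.3, 6.0),
    "ischemic_stroke": (15.0, 1.35, 1.2, 8.0),
    "type_2_diabetes": (250.0, 1.15, 1.0, 3.0),
    "osteoarthritis": (300.0, 1.10, 0.7, 1.2),
    "colorectal_cancer": (5.0, 1.32, 1.2, 12.0),
    "stomach_cancer": (4.0, 1.32, 1.5, 14.0),
}


def _build_strata(population_size: int) -> list[Stratum]:
    """Age-sex strata with exact total, age-graded rates and anthropometry."""
    raw = [population_size * w / 2.0 for w in _AGE_PROFILE for _ in ("male", "female")]
    counts = [int(np.floor(r)) for r in raw]
    order = np.argsort([c - r for c, r in zip(counts, raw)])
    for i in order[: population_size - sum(counts)]:
        counts[i] += 1
    strata: list[Stratum] = []
    i = 0
    for band_idx, band in enumerate(AGE_BANDS):
        for sex in ("male", "female"):
            hm, hs, wm, ws = _ANTHRO[sex]
            incidence: dict[str, float] = {}
            daly: dict[str, float] = {}
            for d, (base, grad, male_mult, dalys_per_case) in _DISEASE_PARAMS.items():
                mult = male_mult if sex == "male" else 1.0
                rate = base * mult * grad**band_idx
                incidence[d] = rate
                daly[d] = rate * dalys_per_case
            strata.append(Stratum(
                age_band=band, sex=sex, population=counts[i],
                incidence=incidence, daly=daly,
                height_mean=hm - 0.002 * band_idx, height_sd=hs,
                weight_mean=wm - 0.3 * band_idx, weight_sd=ws,
            ))
            i += 1
    return strata


# --- relative risks ---------------------------------------------------------

#: fixed point RRs per (risk factor, disease): (RR, increment)
_RR_DEFAULTS: dict[tuple[str, str], tuple[float, float]] = {
    ("sugar", "type_2_diabetes"): (1.10, 50.0),
    ("ssb", "type_2_diabetes"): (1.26, 250.0),
    ("ssb", "ischemic_heart_disease"): (1.17, 250.0),
    ("sfa", "ischemic_heart_disease"): (1.07, 10.0),
    ("sfa", "ischemic_stroke"): (1.02, 10.0),
    ("tfa", "ischemic_heart_disease"): (1.16, 5.0),
    ("tfa", "ischemic_stroke"): (1.05, 5.0),
    ("bmi", "type_2_diabetes"): (2.00, 5.0),
    ("bmi", "ischemic_heart_disease"): (1.50, 5.0),
    ("bmi", "ischemic_stroke"): (1.35, 5.0),
    ("bmi", "osteoarthritis"): (1.30, 5.0),
    ("bmi", "colorectal_cancer"): (1.10, 5.0),
    ("bmi", "stomach_cancer"): (1.05, 5.0),
}


def _rr_table(log_sd: float) -> tuple[RelativeRisk, ...]:
    return tuple(
        RelativeRisk(rf, disease, rr, increment, log_sd)
        for (rf, disease), (rr, increment) in _RR_DEFAULTS.items()
    )


# --- costs ------------------------------------------------------------------

def _default_costs() -> CostCoefficients:
    return CostCoefficients(
        water_price={"agricultural": 10_000.0, "accounting": 30_000.0, "industrial": 60_000.0},
        scc=2_000.0,  # ~USD 50 / tonne CO2e at 2020 exchange rates
        treatment_cost={
            "ischemic_heart_disease": 2.5e8,
            "ischemic_stroke": 4.0e8,
            "type_2_diabetes": 0.8e8,
            "osteoarthritis": 0.5e8,
            "colorectal_cancer": 9.0e8,
            "stomach_cancer": 8.0e8,
        },
        cpi_factor=1.0,
        threshold_br=0.61,
    )


# --- households -------------------------------------------------------------

def _draw_households(config: GeneratorConfig, rng: np.random.Generator,
                     ame_table) -> list[HouseholdRecord]:
    """Households with random rosters and log-normal purchase quantities.

    Quantities are log-normal around mean_quantity x AME units, so the
    per-AME intake is right-skewed and strictly positive (HIES expenditure
    data are right-skewed; log-normal guarantees positivity).
    """
    cv = max(config.quantity_dispersion, 1e-12)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    households = []
    for h in range(config.n_households):
        n_members = 1 + rng.poisson(2.2)
        members = []
        # at least one adult head of household
        members.append(Member(age=float(rng.integers(20, 75)),
                              sex=rng.choice(["male", "female"])))
        for _ in range(n_members - 1):
            members.append(Member(age=float(rng.integers(1, 85)),
                                  sex=rng.choice(["male", "female"])))
        units = ame_units(members, ame_table)
        quantities = {}
        for g in config.food_group_names:
            mean = config.mean_quantity[g] * units
            quantities[g] = float(rng.lognormal(np.log(mean) - sigma**2 / 2, sigma))
        households.append(HouseholdRecord(id=f"hh{h:05d}", members=tuple(members),
                                          quantities=quantities))
    return households


def _draw_elasticities(config: GeneratorConfig, rng: np.random.Generator) -> ElasticityMatrix:
    n = config.n_food_groups
    lo, hi = config.own_elasticity_range
    own = rng.uniform(lo, hi, size=n)
    e = rng.normal(0.0, config.cross_elasticity_scale, size=(n, n))
    for i in range(n):
        # cross terms dominated by the own response, |cross| < |own|
        cap = 0.9 * abs(own[i])
        e[i] = np.clip(e[i], -cap, cap)
        e[i, i] = own[i]
    return ElasticityMatrix(config.food_group_names, e)


def generate_bundle(config: GeneratorConfig) -> InputBundle:
    """Generate a full input bundle; bit-identical for a fixed config."""
    rng = np.random.default_rng(config.seed)
    ame_table = default_ame_table()

    households = _draw_households(config, rng, ame_table)
    elasticities = _draw_elasticities(config, rng)

    # profile quantities are the empirical per-AME means of the households
    mean_per_ame = {g: 0.0 for g in config.food_group_names}
    for hh in households:
        units = ame_units(hh.members, ame_table)
        for g in config.food_group_names:
            mean_per_ame[g] += hh.quantities[g] / units
    for g in mean_per_ame:
        mean_per_ame[g] /= len(households)

    profiles = []
    for g in config.food_group_names:
        if g in _GROUP_DEFAULTS:
            price, _, waste, energy, sugar, sfa, tfa, water, carbon = _GROUP_DEFAULTS[g]
        else:
            price, waste, energy, sugar, sfa, tfa = 200_000.0, 0.10, 800.0, 0.0, 0.0, 0.0
            water, carbon = 1500.0, 2.0
        profiles.append(FoodGroupProfile(
            name=g, price=price, quantity=mean_per_ame[g], waste_fraction=waste,
            energy_density=energy, sugar_content=sugar, sfa_content=sfa,
            tfa_content=tfa, water_footprint=water, carbon_footprint=carbon,
        ))

    # RR point values drawn >1 around the defaults, log-normal uncertainty
    rr_table = []
    for (rf, disease), (rr, increment) in _RR_DEFAULTS.items():
        jitter = float(rng.normal(0.0, 0.02))
        point = max(float(np.exp(np.log(rr) + jitter)), 1.0 + 1e-6)
        rr_table.append(RelativeRisk(rf, disease, point, increment, config.rr_log_sd_scale))

    strata = _build_strata(config.population_size)

    return InputBundle(
        profiles=tuple(profiles),
        households=tuple(households),
        elasticities=elasticities,
        rr_table=tuple(rr_table),
        strata=tuple(strata),
        costs=_default_costs(),
        population_size=config.population_size,
        meta={"seed": config.seed, "n_households": config.n_households,
              "generator": "generate_bundle"},
    )


# --- calibration ------------------------------------------------------------

#: reference scenario definitions: (taxed group, rate)
CALIBRATION_SCENARIOS: dict[str, tuple[str, float]] = {
    "sas25": (SAS, 0.25),
    "ssb30": (SSB, 0.30),
    "hoaf30": (HOAF, 0.30),
}

#: own-group exposure responses the calibration reproduces (percent)
CALIBRATION_TARGETS: dict[str, tuple[str, float]] = {
    "sas25": ("sugar", -10.76),
    "ssb30": ("ssb", -14.26),
    "hoaf30": ("sfa", -7.82),
}

#: additional percent responses encoded in the cross terms, per scenario:
#: {responding group: percent quantity change under the scenario}
_CALIBRATION_CROSS: dict[str, dict[str, float]] = {
    "sas25": {SSB: 1.24, HOAF: -0.40},
    "ssb30": {SAS: -1.96, HOAF: 0.63,
              "red_meat": 0.46, "fruits": 1.39, "vegetables": 1.47, "legumes": 1.89},
    "hoaf30": {SAS: -1.97, SSB: -2.11},
}

_CALIBRATION_OTHER_OWN = {
    "red_meat": -0.45, "fruits": -0.50, "vegetables": -0.40,
    "legumes": -0.35, "bread_and_cereals": -0.25,
}


def _calibration_elasticities() -> ElasticityMatrix:
    """Back-solve the elasticity matrix under the linear response rule.

    With a single taxed group per scenario and full pass-through, the linear
    rule gives %dQ_i = e[i, taxed] x rate x 100, so each encoded response
    pins down one matrix cell: e[i, taxed] = (%dQ_i / 100) / rate.
    """
    groups = DEFAULT_FOOD_GROUPS
    idx = {g: i for i, g in enumerate(groups)}
    e = np.zeros((len(groups), len(groups)))
    for scen, (taxed, rate) in CALIBRATION_SCENARIOS.items():
        rf, target_pct = CALIBRATION_TARGETS[scen]
        # the marker nutrient lives only in the taxed group, so the target
        # is that group's own quantity response
        e[idx[taxed], idx[taxed]] = target_pct / 100.0 / rate
        for responder, pct in _CALIBRATION_CROSS[scen].items():
            e[idx[responder], idx[taxed]] = pct / 100.0 / rate
    for g, own in _CALIBRATION_OTHER_OWN.items():
        e[idx[g], idx[g]] = own
    return ElasticityMatrix(groups, e)


def calibration_bundle(n_households: int = 200, population_size: int = 1_000_000) -> InputBundle:
    """Fixed bundle reproducing the reference own-group exposure responses.

    Elasticities are back-solved (see :func:`_calibration_elasticities`);
    profile quantities are the stated group means rather than household
    empirical means, so the demand-stage responses are exact.  Households
    are generated from an internal fixed seed for the household-level API.
    """
    config = GeneratorConfig(seed=20_2020, n_households=n_households,
                             population_size=population_size)
    rng = np.random.default_rng(config.seed)
    ame_table = default_ame_table()
    households = _draw_households(config, rng, ame_table)

    profiles = tuple(
        FoodGroupProfile(
            name=g, price=_GROUP_DEFAULTS[g][0], quantity=_GROUP_DEFAULTS[g][1],
            waste_fraction=_GROUP_DEFAULTS[g][2], energy_density=_GROUP_DEFAULTS[g][3],
            sugar_content=_GROUP_DEFAULTS[g][4], sfa_content=_GROUP_DEFAULTS[g][5],
            tfa_content=_GROUP_DEFAULTS[g][6], water_footprint=_GROUP_DEFAULTS[g][7],
            carbon_footprint=_GROUP_DEFAULTS[g][8],
        )
        for g in DEFAULT_FOOD_GROUPS
    )

    return InputBundle(
        profiles=profiles,
        households=tuple(households),
        elasticities=_calibration_elasticities(),
        rr_table=_rr_table(log_sd=0.05),
        strata=tuple(_build_strata(population_size)),
        costs=_default_costs(),
        population_size=population_size,
        meta={"seed": config.seed, "generator": "calibration_bundle"},
    )
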