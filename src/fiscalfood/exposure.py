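"""Individual-level nutritional risk-factor exposures.

A simulated adult population (aged 25+) with the age-sex structure of the
stratum table carries five risk factors: sugar, SSB, saturated fat and trans
fat intake (g/day) and BMI (kg/m2).  Dietary exposures derive from the
per-AME basket via nutrient composition; BMI changes follow a steady-state
energy-balance rule: at equilibrium, a sustained change of ``rho`` kJ/day in
intake corresponds to one kilogram of body weight, so

    delta_BMI = (delta_energy / rho) / height**2

with ``rho`` defaulting to 94 kJ/day per kg (about 22.5 kcal/day per kg).
Height and physical activity are held fixed.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, MissingCoefficientError, StructuralError
from .types import FoodGroupProfile, Stratum

__all__ = [
    "Person",
    "Population",
    "scale_strata",
    "build_population",
    "dietary_exposures",
    "delta_bmi",
    "ExposureDelta",
    "scenario_exposure_table",
]

HEIGHT_BOUNDS = (1.2, 2.2)  # m, hard truncation for simulated heights
WEIGHT_BOUNDS = (30.0, 200.0)  # kg
DEFAULT_RHO = 94.0  # kJ/day per kg of steady-state body weight
DEFAULT_BMI_FLOOR = 15.0  # kg/m2, counterfactual BMI never drops below this

DIETARY_FACTORS = ("sugar", "ssb", "sfa", "tfa")


@dataclass(frozen=True)
class Person:
    """One simulated individual (convenience view of a population row)."""

    id: int
    age_band: str
    sex: str
    height: float  # m
    weight: float  # kg

    @property
    def bmi(self) -> float:
        return self.weight / self.height**2


@dataclass
class Population:
    """Simulated individuals, stored columnar for vectorised computation.

    ``frame`` columns: person_id, age_band, sex, height, weight, bmi,
    intake_factor.  Rows are grouped by stratum in the order of the strata
    the population was built from.
    """

    frame: pd.DataFrame
    strata_keys: tuple[tuple[str, str], ...]

    def __len__(self) -> int:
        return len(self.frame)

    def persons(self):
        for row in self.frame.itertuples():
            yield Person(row.person_id, row.age_band, row.sex, row.height, row.weight)

    def stratum_slices(self) -> dict[tuple[str, str], slice]:
        """Contiguous row slice per (age_band, sex) stratum."""
        out: dict[tuple[str, str], slice] = {}
        keys = list(zip(self.frame["age_band"], self.frame["sex"]))
        start = 0
        for key in self.strata_keys:
            end = start
            while end < len(keys) and keys[end] == key:
                end += 1
            out[key] = slice(start, end)
            start = end
        return out


def scale_strata(strata: Sequence[Stratum], n: int) -> list[Stratum]:
    """Rescale stratum counts to total exactly ``n`` (largest remainder).

    Used to simulate a smaller population with the same age-sex structure;
    rates and anthropometry are untouched.
    """
    total = sum(s.population for s in strata)
    if total <= 0:
        raise DomainError("strata have zero total population")
    raw = [s.population * n / total for s in strata]
    counts = [int(np.floor(r)) for r in raw]
    shortfall = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)])  # largest remainder first
    for i in order[:shortfall]:
        counts[i] += 1
    out = []
    for s, c in zip(strata, counts):
        t = Stratum(
            age_band=s.age_band, sex=s.sex, population=c,
            incidence=dict(s.incidence), daly=dict(s.daly),
            height_mean=s.height_mean, height_sd=s.height_sd,
            weight_mean=s.weight_mean, weight_sd=s.weight_sd,
        )
        out.append(t)
    return out


def _truncated_normal(rng, mean, sd, lo, hi, size):
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def build_population(
    n: int,
    strata: Sequence[Stratum],
    seed: int = 0,
    intake_cv: float = 0.0,
) -> Population:
    """Simulate ``n`` individuals allocated to strata in exact proportion.

    Stratum counts must already sum to ``n`` (use :func:`scale_strata`).
    Heights and weights are drawn from per-stratum normal distributions
    truncated to plausible adult ranges; ``intake_cv`` > 0 additionally gives
    each person a log-normal intake multiplier with unit mean, modelling
    person-level dietary heterogeneity.
    """
    counts = [int(round(s.population)) for s in strata]
    if sum(counts) != n:
        raise StructuralError(f"stratum counts sum to {sum(counts)}, expected {n}")
    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for s, c in zip(strata, counts):
        if c == 0:
            continue
        h = _truncated_normal(rng, s.height_mean, s.height_sd, *HEIGHT_BOUNDS, size=c)
        w = _truncated_normal(rng, s.weight_mean, s.weight_sd, *WEIGHT_BOUNDS, size=c)
        if intake_cv > 0:
            sigma = np.sqrt(np.log1p(intake_cv**2))
            factor = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=c)
        else:
            factor = np.ones(c)
        rows.append(pd.DataFrame({
            "person_id": np.arange(pid, pid + c),
            "age_band": s.age_band,
            "sex": s.sex,
            "height": h,
            "weight": w,
            "intake_factor": factor,
        }))
        pid += c
    frame = pd.concat(rows, ignore_index=True)
    frame["bmi"] = frame["weight"] / frame["height"] ** 2
    return Population(frame=frame, strata_keys=tuple(s.key for s in strata if round(s.population)))


def dietary_exposures(
    intake: Mapping[str, float],
    profiles: Sequence[FoodGroupProfile] | Mapping[str, FoodGroupProfile],
) -> dict[str, float]:
    """Map a consumed per-AME basket (g/day per group) to risk-factor amounts.

    Returns sugar/SFA/TFA in g/day (quantity x content per 100 g summed over
    groups), SSB as the consumed grams of the SSB group itself, and total
    energy in kJ/day.
    """
    pmap = profiles if isinstance(profiles, Mapping) else {p.name: p for p in profiles}
    sugar = sfa = tfa = energy = 0.0
    ssb = 0.0
    for group, grams in intake.items():
        try:
            p = pmap[group]
        except KeyError as exc:
            raise MissingCoefficientError(f"no profile for group {group!r}") from exc
        sugar += grams * p.sugar_content / 100.0
        sfa += grams * p.sfa_content / 100.0
        tfa += grams * p.tfa_content / 100.0
        energy += grams * p.energy_density / 100.0
        if group == "ssb":
            ssb += grams
    return {"sugar": sugar, "ssb": ssb, "sfa": sfa, "tfa": tfa, "energy": energy}


def delta_bmi(delta_energy: float | np.ndarray, height: float | np.ndarray,
              rho: float = DEFAULT_RHO):
    """BMI change from a sustained energy-intake change at steady state."""
    if rho <= 0:
        raise DomainError("rho must be > 0")
    height = np.asarray(height, dtype=float)
    if np.any((height <= HEIGHT_BOUNDS[0]) | (height >= HEIGHT_BOUNDS[1])):
        raise DomainError(f"height outside plausible range {HEIGHT_BOUNDS}")
    out = (np.asarray(delta_energy, dtype=float) / rho) / height**2
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExposureDelta:
    """Population-level summary of one risk factor under a scenario."""

    risk_factor: str
    baseline: float
    counterfactual: float

    @property
    def percent_change(self) -> float:
        if self.baseline == 0:
            return 0.0
        return 100.0 * (self.counterfactual - self.baseline) / self.baseline


def scenario_exposure_table(
    population: Population,
    baseline_intake: Mapping[str, float],
    counterfactual_intake: Mapping[str, float],
    profiles: Sequence[FoodGroupProfile] | Mapping[str, FoodGroupProfile],
    rho: float = DEFAULT_RHO,
    bmi_floor: float = DEFAULT_BMI_FLOOR,
) -> tuple[list[ExposureDelta], pd.DataFrame]:
    """Per-person baseline/counterfactual exposures and population means.

    ``baseline_intake`` / ``counterfactual_intake`` are consumed g/day per
    AME per group; each person's dietary exposure is the basket-level value
    scaled by their intake factor.  Counterfactual BMI adds the energy-
    balance shift and is floored at ``bmi_floor``.

    Returns the per-risk-factor :class:`ExposureDelta` list and a frame with
    ``base_<rf>`` / ``cf_<rf>`` columns per person.
    """
    if set(baseline_intake) != set(counterfactual_intake):
        raise StructuralError("baseline and counterfactual baskets cover different groups")
    base = dietary_exposures(baseline_intake, profiles)
    cf = dietary_exposures(counterfactual_intake, profiles)

    frame = population.frame
    factor = frame["intake_factor"].to_numpy()
    per_person = pd.DataFrame({
        "person_id": frame["person_id"],
        "age_band": frame["age_band"],
        "sex": frame["sex"],
    })
    for rf in DIETARY_FACTORS:
        per_person[f"base_{rf}"] = base[rf] * factor
        per_person[f"cf_{rf}"] = cf[rf] * factor

    d_energy = (cf["energy"] - base["energy"]) * factor
    bmi0 = frame["bmi"].to_numpy()
    # the floor stops the energy shift driving BMI implausibly low, but never
    # lifts someone whose baseline is already below it
    floor = np.minimum(bmi_floor, bmi0)
    bmi1 = np.maximum(bmi0 + delta_bmi(d_energy, frame["height"].to_numpy(), rho), floor)
    per_person["base_bmi"] = bmi0
    per_person["cf_bmi"] = bmi1

    deltas = [
        ExposureDelta(rf, float(per_person[f"base_{rf}"].mean()),
                      float(per_person[f"cf_{rf}"].mean()))
        for rf in (*DIETARY_FACTORS, "bmi")
    ]
    return deltas, per_person
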