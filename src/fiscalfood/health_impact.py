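"""Relative-risk scaling, population impact fractions and averted burden.

The relative risk at an arbitrary exposure ``M`` scales the per-increment
risk on the log scale:

    RR(M) = exp( ln(RR_per_x) * M / x )

so one increment of exposure returns the tabulated RR exactly and zero
exposure returns 1.  The population impact fraction over individuals i is

    PIF = 1 - sum_i RR(M*_i) / sum_i RR(M_i)

with M* the counterfactual exposure.  PIFs from several risk factors acting
on the same disease combine multiplicatively on the survival scale,
``1 - prod(1 - PIF_r)``, the standard independence assumption.  Applied to
stratum-level incidence and DALY rates the PIF yields averted incident cases
and averted DALYs.

BMI enters the RR equation as exposure above a theoretical-minimum-risk
level (default 22 kg/m2): a per-unit RR anchored at zero BMI would be
biologically meaningless.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import DomainError, MissingCoefficientError, StructuralError
from .types import DISEASES, RelativeRisk, Stratum

__all__ = [
    "rr_at_exposure",
    "population_impact_fraction",
    "combine_pifs",
    "averted_burden",
    "incidence_percent_change",
    "default_risk_outcome_map",
    "bmi_excess",
    "DiseaseBurden",
    "HealthImpactResult",
    "scenario_health_impact",
    "DEFAULT_BMI_TMREL",
]

DEFAULT_BMI_TMREL = 22.0  # kg/m2, theoretical-minimum-risk BMI


def rr_at_exposure(rr: RelativeRisk, exposure):
    """Relative risk at ``exposure`` units (scalar or array)."""
    if rr.rr_per_increment <= 0:
        raise DomainError("rr_per_increment must be > 0")
    out = np.exp(np.log(rr.rr_per_increment) * np.asarray(exposure, dtype=float) / rr.increment)
    return float(out) if out.ndim == 0 else out


def population_impact_fraction(
    baseline_exposures: Sequence[float] | np.ndarray,
    counterfactual_exposures: Sequence[float] | np.ndarray,
    rr: RelativeRisk,
) -> float:
    """PIF of shifting paired individual exposures from baseline to
    counterfactual; positive when risk falls."""
    base = np.asarray(baseline_exposures, dtype=float)
    cf = np.asarray(counterfactual_exposures, dtype=float)
    if base.size == 0 or base.shape != cf.shape:
        raise StructuralError("exposure lists must be non-empty and of equal length")
    return float(1.0 - rr_at_exposure(rr, cf).sum() / rr_at_exposure(rr, base).sum())


def combine_pifs(pifs: Sequence[float]) -> float:
    """Multiplicative (independent-risk) combination, 1 - prod(1 - p)."""
    pifs = np.asarray(pifs, dtype=float)
    if np.any(pifs > 1):
        raise DomainError("a PIF cannot exceed 1")
    return float(1.0 - np.prod(1.0 - pifs))


def bmi_excess(bmi, tmrel: float = DEFAULT_BMI_TMREL):
    """BMI exposure above the theoretical-minimum-risk level, floored at 0."""
    return np.maximum(np.asarray(bmi, dtype=float) - tmrel, 0.0)


def default_risk_outcome_map() -> dict[str, tuple[str, ...]]:
    """Packaged risk-factor -> diseases mapping (editable data, not code)."""
    path = resources.files("fiscalfood.data") / "risk_outcome_map.yaml"
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {rf: tuple(ds) for rf, ds in raw.items()}


@dataclass
class DiseaseBurden:
    """Averted burden of one disease, by stratum and total."""

    disease: str
    pif_by_stratum: dict[tuple[str, str], float]
    averted_cases_by_stratum: dict[tuple[str, str], float]
    averted_dalys_by_stratum: dict[tuple[str, str], float]

    @property
    def averted_cases(self) -> float:
        return sum(self.averted_cases_by_stratum.values())

    @property
    def averted_dalys(self) -> float:
        return sum(self.averted_dalys_by_stratum.values())


@dataclass
class HealthImpactResult:
    """All-disease health impact of one scenario."""

    scenario: str
    burdens: dict[str, DiseaseBurden]
    incidence_pct_change: dict[str, float] = field(default_factory=dict)

    @property
    def averted_cases_by_disease(self) -> dict[str, float]:
        return {d: b.averted_cases for d, b in self.burdens.items()}

    @property
    def total_averted_dalys(self) -> float:
        return sum(b.averted_dalys for b in self.burdens.values())

    @property
    def total_averted_cases(self) -> float:
        return sum(b.averted_cases for b in self.burdens.values())


def averted_burden(
    pif_by_stratum: Mapping[tuple[str, str], float],
    strata: Sequence[Stratum],
    disease: str,
) -> DiseaseBurden:
    """Averted cases and DALYs: PIF x rate x population / 100,000 per cell."""
    cases: dict[tuple[str, str], float] = {}
    dalys: dict[tuple[str, str], float] = {}
    for s in strata:
        try:
            pif = pif_by_stratum[s.key]
        except KeyError as exc:
            raise MissingCoefficientError(f"no PIF for stratum {s.key}") from exc
        if disease not in s.incidence or disease not in s.daly:
            raise MissingCoefficientError(f"stratum {s.key} lacks rates for {disease!r}")
        cases[s.key] = pif * s.incidence[disease] * s.population / 1e5
        dalys[s.key] = pif * s.daly[disease] * s.population / 1e5
    return DiseaseBurden(disease, dict(pif_by_stratum), cases, dalys)


def incidence_percent_change(
    pif_by_stratum: Mapping[tuple[str, str], float],
    strata: Sequence[Stratum],
    disease: str,
) -> float:
    """Percent change in the age-sex-standardised incidence rate.

    Equals -100 x sum(pif x rate x pop) / sum(rate x pop); standardisation
    uses the simulated population's own structure as the weights.
    """
    num = den = 0.0
    for s in strata:
        try:
            rate = s.incidence[disease]
        except KeyError as exc:
            raise MissingCoefficientError(f"stratum {s.key} lacks rates for {disease!r}") from exc
        pif = pif_by_stratum[s.key]
        num += pif * rate * s.population
        den += rate * s.population
    if den == 0:
        raise DomainError(f"total incidence of {disease!r} is zero")
    return -100.0 * num / den


def scenario_health_impact(
    per_person: pd.DataFrame,
    rr_table: Sequence[RelativeRisk],
    strata: Sequence[Stratum],
    scenario: str = "",
    risk_outcome_map: Mapping[str, Sequence[str]] | None = None,
    bmi_tmrel: float = DEFAULT_BMI_TMREL,
) -> HealthImpactResult:
    """Full health-impact computation for one scenario.

    ``per_person`` is the frame from
    :func:`fiscalfood.exposure.scenario_exposure_table` (columns
    ``base_<rf>`` / ``cf_<rf>`` plus age_band and sex).  PIFs are computed
    within each age-sex stratum for every (risk factor, disease) pair in the
    RR table that the risk-outcome map admits, combined multiplicatively per
    disease, then applied to the full stratum populations in ``strata``
    (which may be much larger than the simulated sample).
    """
    rom = {rf: tuple(ds) for rf, ds in (risk_outcome_map or default_risk_outcome_map()).items()}
    pairs = [rr for rr in rr_table if rr.disease in rom.get(rr.risk_factor, ())]

    sim_keys = list(dict.fromkeys(zip(per_person["age_band"], per_person["sex"])))
    groups = {key: np.asarray(idx) for key, idx in
              per_person.groupby(["age_band", "sex"], sort=False).indices.items()}

    burdens: dict[str, DiseaseBurden] = {}
    pct: dict[str, float] = {}
    for disease in DISEASES:
        disease_pairs = [rr for rr in pairs if rr.disease == disease]
        pif_by_stratum: dict[tuple[str, str], float] = {}
        for key in sim_keys:
            idx = groups[key]
            pifs = []
            for rr in disease_pairs:
                b = per_person[f"base_{rr.risk_factor}"].to_numpy()[idx]
                c = per_person[f"cf_{rr.risk_factor}"].to_numpy()[idx]
                if rr.risk_factor == "bmi":
                    b, c = bmi_excess(b, bmi_tmrel), bmi_excess(c, bmi_tmrel)
                pifs.append(population_impact_fraction(b, c, rr))
            pif_by_stratum[key] = combine_pifs(pifs) if pifs else 0.0
        present = [s for s in strata if s.key in pif_by_stratum]
        if len(present) != len(strata):
            missing = [s.key for s in strata if s.key not in pif_by_stratum]
            raise StructuralError(f"simulated population lacks strata {missing}")
        burdens[disease] = averted_burden(pif_by_stratum, strata, disease)
        pct[disease] = incidence_percent_change(pif_by_stratum, strata, disease)
    return HealthImpactResult(scenario=scenario, burdens=burdens, incidence_pct_change=pct)
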