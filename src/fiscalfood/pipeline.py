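"""End-to-end scenario evaluation.

``run_scenario`` chains the stages deterministically: tax -> demand response
-> waste-adjusted per-AME intakes -> person-level exposures over a simulated
age-sex-structured population -> stratum PIFs -> averted cases/DALYs ->
footprints -> cost ledger -> ICER.  The Monte-Carlo wrapper in
:mod:`fiscalfood.uncertainty` reruns exactly this function per draw.

The simulated sample (default 10,000 persons) estimates the PIFs; burdens
and costs are then scaled to the bundle's full reference population
(default one million adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .demand import adjust_for_waste, apply_tax_scenario
from .economics import (
    CostLedger,
    ICERResult,
    assemble_ledger,
    environmental_cost,
    healthcare_cost,
    household_cost,
    icer,
)
from .environment import FootprintResult, footprint_change
from .exposure import (
    DEFAULT_BMI_FLOOR,
    DEFAULT_RHO,
    ExposureDelta,
    Population,
    build_population,
    scale_strata,
    scenario_exposure_table,
)
from .health_impact import DEFAULT_BMI_TMREL, HealthImpactResult, scenario_health_impact
from .types import InputBundle, TaxScenario

__all__ = ["ScenarioResult", "run_scenario"]


@dataclass
class ScenarioResult:
    """All outputs of one deterministic scenario run."""

    scenario: str
    exposure_deltas: list[ExposureDelta]
    per_person: pd.DataFrame
    health: HealthImpactResult
    footprint: FootprintResult
    ledger: CostLedger
    icer_result: ICERResult | None  # None when the scenario averts no DALYs
    meta: dict = field(default_factory=dict)

    def summary(self) -> dict[str, float]:
        """Flat numeric summary (one value per reported quantity)."""
        out: dict[str, float] = {}
        for d in self.exposure_deltas:
            out[f"pct_change_{d.risk_factor}"] = d.percent_change
        for disease, pct in self.health.incidence_pct_change.items():
            out[f"incidence_pct_{disease}"] = pct
        out["water_pct_change"] = self.footprint.water_pct_change
        out["carbon_pct_change"] = self.footprint.carbon_pct_change
        out["dalys_averted"] = self.health.total_averted_dalys
        out["cases_averted"] = self.health.total_averted_cases
        out["cost_household"] = self.ledger.household
        out["cost_water"] = self.ledger.water
        out["cost_carbon"] = self.ledger.carbon
        out["cost_healthcare"] = self.ledger.healthcare
        out["cost_total"] = self.ledger.total
        out["icer"] = self.icer_result.icer if self.icer_result else float("nan")
        return out

    def exposure_frame(self) -> pd.DataFrame:
        """Risk-factor summary in the export layout."""
        return pd.DataFrame([
            {"risk_factor": d.risk_factor, "baseline_mean": d.baseline,
             "counterfactual_mean": d.counterfactual, "percent_change": d.percent_change}
            for d in self.exposure_deltas
        ])


def run_scenario(
    bundle: InputBundle,
    scenario: TaxScenario,
    n_persons: int = 10_000,
    seed: int = 0,
    rho: float = DEFAULT_RHO,
    bmi_floor: float = DEFAULT_BMI_FLOOR,
    bmi_tmrel: float = DEFAULT_BMI_TMREL,
    water_variant: str = "agricultural",
    response: str = "linear",
    intake_cv: float = 0.0,
    population: Population | None = None,
) -> ScenarioResult:
    """Evaluate one tax scenario against the no-tax baseline.

    ``population`` may be passed in to reuse the same simulated individuals
    across runs (the uncertainty wrapper does this); otherwise ``n_persons``
    are simulated from the bundle's strata with ``seed``.
    """
    baseline_basket = list(bundle.profiles)
    counterfactual_basket = apply_tax_scenario(
        baseline_basket, bundle.elasticities, scenario, response=response
    )

    base_intake = {p.name: adjust_for_waste(p.quantity, p.waste_fraction)
                   for p in baseline_basket}
    cf_intake = {p.name: adjust_for_waste(p.quantity, p.waste_fraction)
                 for p in counterfactual_basket}

    if population is None:
        strata_n = scale_strata(bundle.strata, n_persons)
        population = build_population(n_persons, strata_n, seed=seed, intake_cv=intake_cv)

    deltas, per_person = scenario_exposure_table(
        population, base_intake, cf_intake, bundle.profiles,
        rho=rho, bmi_floor=bmi_floor,
    )

    health = scenario_health_impact(
        per_person, bundle.rr_table, bundle.strata,
        scenario=scenario.name, bmi_tmrel=bmi_tmrel,
    )

    fp = footprint_change(
        {p.name: p.quantity for p in baseline_basket},
        {p.name: p.quantity for p in counterfactual_basket},
        bundle.profiles, scenario=scenario.name,
    )

    scale = bundle.population_size * 365.0
    hh_cost = household_cost(baseline_basket, counterfactual_basket, population_scale=scale)
    water_cost, carbon_cost = environmental_cost(
        fp, bundle.costs, water_variant=water_variant, population_scale=scale
    )
    hc_cost = healthcare_cost(health.averted_cases_by_disease,
                              bundle.costs.treatment_cost, bundle.costs.cpi_factor)
    ledger = assemble_ledger(hh_cost, water_cost, carbon_cost, hc_cost,
                             scenario=scenario.name)
    # a no-effect scenario (e.g. all rates zero) has no defined ICER
    dalys = health.total_averted_dalys
    ic = (icer(ledger, dalys, threshold=bundle.costs.threshold_br)
          if dalys != 0 else None)

    return ScenarioResult(
        scenario=scenario.name,
        exposure_deltas=deltas,
        per_person=per_person,
        health=health,
        footprint=fp,
        ledger=ledger,
        icer_result=ic,
        meta={"n_persons": len(population), "seed": seed, "water_variant": water_variant,
              "rho": rho, "response": response},
    )
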