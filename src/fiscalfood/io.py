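"""Bundle and scenario persistence.

An :class:`~fiscalfood.types.InputBundle` round-trips through a directory of
plain CSV tables (food_groups.csv, households.csv, members.csv,
elasticities.csv, rr_table.csv, strata.csv, footprints.csv, costs.csv,
waste.csv) plus a YAML manifest recording provenance.  Tax scenarios load
from small YAML files; the three reference scenarios ship with the package.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .types import (
    DISEASES,
    CostCoefficients,
    ElasticityMatrix,
    FoodGroupProfile,
    HouseholdRecord,
    InputBundle,
    Member,
    RelativeRisk,
    Stratum,
    TaxScenario,
)

__all__ = ["write_bundle", "read_bundle", "load_scenario", "packaged_scenario"]

_PROFILE_COLS = ["name", "price", "quantity", "energy_density",
                 "sugar_content", "sfa_content", "tfa_content"]


def write_bundle(bundle: InputBundle, directory: str | Path) -> Path:
    """Write a bundle as CSV tables plus a YAML manifest; returns the dir."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    pd.DataFrame([{c: getattr(p, c) for c in _PROFILE_COLS} for p in bundle.profiles]
                 ).to_csv(d / "food_groups.csv", index=False, float_format="%.17g")
    pd.DataFrame([{"group": p.name, "waste_fraction": p.waste_fraction}
                  for p in bundle.profiles]).to_csv(d / "waste.csv", index=False, float_format="%.17g")
    pd.DataFrame([{"group": p.name, "water_l_per_kg": p.water_footprint,
                   "carbon_kgco2e_per_kg": p.carbon_footprint}
                  for p in bundle.profiles]).to_csv(d / "footprints.csv", index=False, float_format="%.17g")

    em = pd.DataFrame(bundle.elasticities.e, index=list(bundle.elasticities.groups),
                      columns=list(bundle.elasticities.groups))
    em.to_csv(d / "elasticities.csv", index_label="group", float_format="%.17g")

    hh_rows, member_rows = [], []
    for hh in bundle.households:
        hh_rows.append({"household_id": hh.id, **{g: q for g, q in hh.quantities.items()}})
        for m in hh.members:
            member_rows.append({"household_id": hh.id, "age": m.age, "sex": m.sex})
    pd.DataFrame(hh_rows).to_csv(d / "households.csv", index=False, float_format="%.17g")
    pd.DataFrame(member_rows).to_csv(d / "members.csv", index=False)

    pd.DataFrame([rr.__dict__ for rr in bundle.rr_table]).to_csv(d / "rr_table.csv", index=False, float_format="%.17g")

    strata_rows = []
    for s in bundle.strata:
        row = {"age_band": s.age_band, "sex": s.sex, "population": s.population,
               "height_mean": s.height_mean, "height_sd": s.height_sd,
               "weight_mean": s.weight_mean, "weight_sd": s.weight_sd}
        for dd in DISEASES:
            row[f"incidence_{dd}"] = s.incidence.get(dd, 0.0)
            row[f"daly_{dd}"] = s.daly.get(dd, 0.0)
        strata_rows.append(row)
    pd.DataFrame(strata_rows).to_csv(d / "strata.csv", index=False, float_format="%.17g")

    cost_rows = [{"category": "water_price", "key": k, "value": v}
                 for k, v in bundle.costs.water_price.items()]
    cost_rows.append({"category": "scc", "key": "", "value": bundle.costs.scc})
    cost_rows += [{"category": "treatment_cost", "key": k, "value": v}
                  for k, v in bundle.costs.treatment_cost.items()]
    if isinstance(bundle.costs.cpi_factor, dict):
        cost_rows += [{"category": "cpi_factor", "key": k, "value": v}
                      for k, v in bundle.costs.cpi_factor.items()]
    else:
        cost_rows.append({"category": "cpi_factor", "key": "", "value": bundle.costs.cpi_factor})
    cost_rows.append({"category": "threshold_br", "key": "", "value": bundle.costs.threshold_br})
    pd.DataFrame(cost_rows).to_csv(d / "costs.csv", index=False, float_format="%.17g")

    manifest = {"population_size": int(bundle.population_size),
                "meta": {k: (int(v) if isinstance(v, (int, np.integer)) else v)
                         for k, v in bundle.meta.items()}}
    (d / "manifest.yaml").write_text(yaml.safe_dump(manifest), encoding="utf-8")
    return d


def read_bundle(directory: str | Path) -> InputBundle:
    """Read a bundle written by :func:`write_bundle`."""
    d = Path(directory)
    manifest = yaml.safe_load((d / "manifest.yaml").read_text(encoding="utf-8"))

    fg = pd.read_csv(d / "food_groups.csv", float_precision="round_trip")
    waste = pd.read_csv(d / "waste.csv", float_precision="round_trip").set_index("group")["waste_fraction"]
    fp = pd.read_csv(d / "footprints.csv", float_precision="round_trip").set_index("group")
    profiles = tuple(
        FoodGroupProfile(
            name=r["name"], price=r["price"], quantity=r["quantity"],
            waste_fraction=float(waste[r["name"]]),
            energy_density=r["energy_density"], sugar_content=r["sugar_content"],
            sfa_content=r["sfa_content"], tfa_content=r["tfa_content"],
            water_footprint=float(fp.loc[r["name"], "water_l_per_kg"]),
            carbon_footprint=float(fp.loc[r["name"], "carbon_kgco2e_per_kg"]),
        )
        for _, r in fg.iterrows()
    )

    em = pd.read_csv(d / "elasticities.csv", index_col="group", float_precision="round_trip")
    elasticities = ElasticityMatrix(list(em.index), em.to_numpy())

    members = pd.read_csv(d / "members.csv", float_precision="round_trip")
    by_hh = {hid: tuple(Member(float(r.age), str(r.sex)) for r in grp.itertuples())
             for hid, grp in members.groupby("household_id", sort=False)}
    hh = pd.read_csv(d / "households.csv", float_precision="round_trip")
    groups = [c for c in hh.columns if c != "household_id"]
    households = tuple(
        HouseholdRecord(id=str(r["household_id"]), members=by_hh[r["household_id"]],
                        quantities={g: float(r[g]) for g in groups})
        for _, r in hh.iterrows()
    )

    rrt = pd.read_csv(d / "rr_table.csv", float_precision="round_trip")
    rr_table = tuple(
        RelativeRisk(r.risk_factor, r.disease, float(r.rr_per_increment),
                     float(r.increment), float(r.log_sd))
        for r in rrt.itertuples()
    )

    st = pd.read_csv(d / "strata.csv", float_precision="round_trip")
    strata = tuple(
        Stratum(
            age_band=str(r["age_band"]), sex=str(r["sex"]), population=float(r["population"]),
            incidence={dd: float(r[f"incidence_{dd}"]) for dd in DISEASES},
            daly={dd: float(r[f"daly_{dd}"]) for dd in DISEASES},
            height_mean=float(r["height_mean"]), height_sd=float(r["height_sd"]),
            weight_mean=float(r["weight_mean"]), weight_sd=float(r["weight_sd"]),
        )
        for _, r in st.iterrows()
    )

    costs_df = pd.read_csv(d / "costs.csv", float_precision="round_trip").fillna({"key": ""})
    water_price, treatment, cpi_map = {}, {}, {}
    scc = cpi_scalar = threshold = None
    for r in costs_df.itertuples():
        if r.category == "water_price":
            water_price[str(r.key)] = float(r.value)
        elif r.category == "scc":
            scc = float(r.value)
        elif r.category == "treatment_cost":
            treatment[str(r.key)] = float(r.value)
        elif r.category == "cpi_factor":
            if str(r.key):
                cpi_map[str(r.key)] = float(r.value)
            else:
                cpi_scalar = float(r.value)
        elif r.category == "threshold_br":
            threshold = float(r.value)
    costs = CostCoefficients(
        water_price=water_price, scc=scc, treatment_cost=treatment,
        cpi_factor=cpi_map if cpi_map else (cpi_scalar if cpi_scalar is not None else 1.0),
        threshold_br=threshold if threshold is not None else 0.61,
    )

    return InputBundle(
        profiles=profiles, households=households, elasticities=elasticities,
        rr_table=rr_table, strata=strata, costs=costs,
        population_size=int(manifest["population_size"]),
        meta=dict(manifest.get("meta", {})),
    )


def load_scenario(path: str | Path) -> TaxScenario:
    """Load a tax scenario from a YAML file (name, rates map, pass_through)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    try:
        return TaxScenario(
            name=str(raw["name"]),
            rates={str(g): float(r) for g, r in raw["rates"].items()},
            pass_through=float(raw.get("pass_through", 1.0)),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed scenario file {path}: {exc}") from exc


def packaged_scenario(name: str) -> TaxScenario:
    """Load one of the shipped scenarios: 'sas25', 'ssb30' or 'hoaf30'."""
    res = resources.files("fiscalfood.data") / "scenarios" / f"{name}.yaml"
    if not res.is_file():
        raise ConfigurationError(f"no packaged scenario named {name!r}")
    raw = yaml.safe_load(res.read_text(encoding="utf-8"))
    return TaxScenario(name=str(raw["name"]),
                       rates={str(g): float(r) for g, r in raw["rates"].items()},
                       pass_through=float(raw.get("pass_through", 1.0)))
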