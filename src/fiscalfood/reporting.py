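"""CSV/YAML result exports.

Writes, per run directory: table1.csv (risk-factor percent changes),
table2.csv (incidence percent changes per disease), table3.csv (cost ledger,
DALYs and ICER), footprints.csv, optionally sensitivity.csv, and a
run-manifest YAML.  Two-decimal rounding happens only here, never inside
the computation.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from pathlib import Path

import pandas as pd
import yaml

from .pipeline import ScenarioResult
from .types import DISEASES
from .uncertainty import IntervalEstimate

__all__ = ["write_results"]


def _ui(intervals: Mapping[str, IntervalEstimate] | None, key: str):
    if intervals and key in intervals:
        iv = intervals[key]
        return iv.lower, iv.upper
    return float("nan"), float("nan")


def write_results(
    outdir: str | Path,
    results: Sequence[ScenarioResult],
    intervals: Mapping[str, Mapping[str, IntervalEstimate]] | None = None,
    sensitivity: pd.DataFrame | None = None,
    manifest: Mapping | None = None,
) -> Path:
    """Write result tables for one or more scenarios; returns the dir.

    ``intervals`` maps scenario name -> summary-key -> interval, as produced
    by :func:`fiscalfood.uncertainty.run_with_uncertainty`.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    intervals = intervals or {}

    t1_rows, t2_rows, t3_rows, fp_rows = [], [], [], []
    for res in results:
        ivs = intervals.get(res.scenario)
        for d in res.exposure_deltas:
            lo, hi = _ui(ivs, f"pct_change_{d.risk_factor}")
            t1_rows.append({
                "scenario": res.scenario, "risk_factor": d.risk_factor,
                "baseline_mean": d.baseline, "counterfactual_mean": d.counterfactual,
                "percent_change": round(d.percent_change, 2),
                "lower_ui": round(lo, 2), "upper_ui": round(hi, 2),
            })
        for disease in DISEASES:
            lo, hi = _ui(ivs, f"incidence_pct_{disease}")
            t2_rows.append({
                "scenario": res.scenario, "disease": disease,
                "incidence_percent_change": round(res.health.incidence_pct_change[disease], 3),
                "lower_ui": round(lo, 3), "upper_ui": round(hi, 3),
            })
        row = {"scenario": res.scenario}
        for key, label in [("cost_household", "household_costs_br"),
                           ("cost_water", "water_costs_br"),
                           ("cost_carbon", "carbon_costs_br"),
                           ("cost_healthcare", "healthcare_costs_br"),
                           ("cost_total", "total_costs_br"),
                           ("dalys_averted", "total_dalys_averted"),
                           ("icer", "icer_br_per_daly")]:
            value = res.summary()[key]
            lo, hi = _ui(ivs, key)
            row[label] = round(value, 2)
            row[f"{label}_lower"] = round(lo, 2)
            row[f"{label}_upper"] = round(hi, 2)
        row["cost_effective"] = bool(res.icer_result and res.icer_result.cost_effective)
        t3_rows.append(row)
        fp_rows.append({
            "scenario": res.scenario,
            "water_baseline_l_per_ame_day": res.footprint.water_baseline,
            "water_counterfactual": res.footprint.water_counterfactual,
            "water_pct_change": round(res.footprint.water_pct_change, 2),
            "carbon_baseline_kg_per_ame_day": res.footprint.carbon_baseline,
            "carbon_counterfactual": res.footprint.carbon_counterfactual,
            "carbon_pct_change": round(res.footprint.carbon_pct_change, 2),
        })

    pd.DataFrame(t1_rows).to_csv(out / "table1.csv", index=False)
    pd.DataFrame(t2_rows).to_csv(out / "table2.csv", index=False)
    pd.DataFrame(t3_rows).to_csv(out / "table3.csv", index=False)
    pd.DataFrame(fp_rows).to_csv(out / "footprints.csv", index=False)
    if sensitivity is not None:
        sensitivity.to_csv(out / "sensitivity.csv", index=False)
    if manifest is not None:
        (out / "run_manifest.yaml").write_text(yaml.safe_dump(dict(manifest)), encoding="utf-8")
    return out
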