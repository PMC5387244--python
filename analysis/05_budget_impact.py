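#!/usr/bin/env python
"""Budget impact: per-patient avoidable costs scaled to the annual NHS cohort.

Multiplies each scenario's pound-rounded avoidable cost by 106 treated
patients per year and writes results/budget_impact.csv.

Finding: annual-cohort savings are £14,522 (scenario 1), £37,100 (scenario 2)
and £95,188 (scenario 3) — modest at health-system scale, which is the point:
initial stenting success is already high, so the headroom is small.
"""

from pathlib import Path

import pandas as pd

from coarctcost.report import budget_impact, build_report, round_pounds, to_usd
from coarctcost.scenarios import builtin_scenarios
from coarctcost.synthetic import baseline_2014

OUT = Path(__file__).resolve().parents[1] / "results"
PATIENTS_PER_YEAR = 106


def main() -> None:
    report = build_report(baseline_2014(), builtin_scenarios())
    rows = []
    for name in ("Scenario 1", "Scenario 2", "Scenario 3", "Best case"):
        per_patient = report[name]["avoidable_vs_baseline"]
        bi = budget_impact(per_patient, PATIENTS_PER_YEAR)
        rows.append(
            {
                "scenario": name,
                "avoidable_per_patient_gbp": per_patient,
                "patients_per_year": PATIENTS_PER_YEAR,
                "annual_savings_gbp": round_pounds(bi.total_savings),
                "annual_savings_usd": round_pounds(to_usd(bi.total_savings)),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "budget_impact.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nwritten to {OUT / 'budget_impact.csv'}")


if __name__ == "__main__":
    main()
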