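# coarctcost

A decision-analytic cost model of **stent repair for coarctation of the aorta
(CoA)**, for health-economics analysts and clinical researchers who want to
quantify the costs that better treatment outcomes could avoid.

Coarctation of the aorta is a congenital narrowing of the aorta, commonly
repaired by stent implantation. The procedure succeeds (post-treatment
gradient ≤ 20 mmHg) in most patients, but aortic wall injuries (AWI),
re-coarctation, reinterventions at follow-up, and long-running
anti-hypertensive medication all add cost. This package prices that pathway
and asks: *how much of the expected cost is avoidable if care improves?*

## The model

A cohort decision tree over three periods — the initial intervention,
short-term follow-up (3–18 months), and mid-term follow-up (18 months–5
years). Each chance node contributes its probability-weighted branch costs:

```
E[initial]  = p_succ · C_stent_ev + (1 − p_succ) · [c_stent + p_rep · C_stent_ev + (1 − p_rep) · c_surg]
C_stent_ev  = c_stent + p_awi · [p_perc · c_awi_int + (1 − p_perc) · c_awi_surg]
E[follow-up] = p_img · c_img + p_htn · c_htn · years + p_reint · [p_ra · C_awi_repair + (1 − p_ra) · C_stent_ev]
E[total]    = E[initial] + E[short] · (1.035)^−0.875 + E[mid] · (1.035)^−3.25
```

Follow-up periods are discounted at the standard NHS rate of 3.5 %/year to
their midpoints. The *avoidable cost* of a scenario is the baseline expected
total minus the scenario's, computed on unrounded values. Parameter
uncertainty propagates through a probabilistic sensitivity analysis (PSA):
probabilities get moment-matched beta distributions, costs moment-matched
gamma distributions, and the model is evaluated per draw.

The baseline parameters (GBP, 2014 prices, NHS reference costs) ship with the
package (`coarctcost/data/baseline_2014.yaml`), as do the four improvement
scenarios (complications ↓10 %; ↓25 % with medication ↓10 %; guaranteed
success with complications ↓50 % and medication ↓25 %; and an ideal best
case).

## Worked example

```python
from coarctcost import baseline_2014, builtin_scenarios, build_report

report = build_report(baseline_2014(), builtin_scenarios())
print(report)
```

prints (GBP, rounded to the pound):

```
                      Baseline  Scenario 1  Scenario 2  Scenario 3  Best case
initial                   4790        4781        4769        4550       4508
short_term                5980        5933        5861        5741       5492
mid_term                  5918        5836        5709        5498       5061
overall                  16688       16551       16338       15790      15061
avoidable_vs_baseline     <NA>         137         350         898       1627
```

Expected cost of the baseline pathway is £16,688 per patient over five years.
Even the best case — guaranteed success with zero complications and no
medication — avoids only £1627 (≈ 10 %); the realistic improvement scenarios
avoid £137–£898. Scaled to an annual NHS cohort of 106 patients, scenario 3
saves about £95,188 per year (`analysis/05_budget_impact.py`).

The same computations are available from the shell:

```bash
coarctcost run --out table.csv
coarctcost tornado --delta 0.1
coarctcost oneway --param reintervention --from 0 --to 2 --steps 21
coarctcost psa --n 1000 --seed 42 --sd-scale 1.0
coarctcost budget --scenario 3 --patients 106
```

## Analysis scripts

The numbered drivers under `analysis/` narrate the full study and write their
tables under `results/`: `01_base_case.py` (the table above),
`02_tornado.py` (±10 % ranking — imaging cost, stent cost and success
probability dominate), `03_oneway_reintervention.py` (the
baseline-vs-scenario-3 gap runs from £258 at zero reinterventions to £1538 at
doubled rates), `04_psa.py` (1000 draws plus the SD-doubling rerun), and
`05_budget_impact.py`.

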