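# Methods

## Model structure

`coarctcost` is a cohort expected-value decision tree for stent repair of
coarctation of the aorta, evaluated over three periods. There is no
mortality, no utilities/QALYs, and no horizon beyond five years: the output
is cost only, from the health-care provider's perspective (direct costs,
GBP 2014).

**Initial intervention.** The first chance node is treatment success
(post-intervention gradient ≤ 20 mmHg). A *stenting event* costs the stent
procedure plus, with probability `p_awi`, the repair of an aortic wall injury
(AWI), itself a mix of percutaneous and surgical repair. Patients whose
initial stent fails incur the initial stent cost **plus** a second
intervention — repeat stenting (again carrying AWI risk) or surgery, split by
`p_repeat_stent`. This additive failure-branch accounting is the convention
under which the engine's period costs agree with the brute-force tree
enumeration and with the published base case.

**Follow-up periods** (short-term, 3–18 months; mid-term, 18 months–5 years)
each add: an imaging cost (the imaging probability is 1 at baseline); the
annual anti-hypertensive medication cost, scaled by the medicated share and a
period year-multiplier; and an expected reintervention cost. A reintervention
is an AWI repair with probability `p_reint_awi` and otherwise a
re-coarctation restent, costed exactly like a successful initial stenting
event (no success/failure split and no surgery option at follow-up).

**Complement handling.** Event pairs that must sum to one (surgery vs repeat
stent, surgical vs percutaneous AWI repair, re-CoA vs AWI reintervention) are
stored once; the complement is always derived, never configured, so the pair
cannot drift.

## Discounting and timing

Follow-up costs are discounted as lump sums at the period midpoints —
0.875 years (10.5 months) for short-term and 3.25 years (39 months) for
mid-term — at the standard NHS rate of 3.5 %/year; the initial period is at
t = 0. The hypertension cost accrues for one year in the short-term period
and two years in the mid-term period. Both conventions are exposed on
`DiscountSpec` (`t_short`, `t_mid`, `htn_years_short`, `htn_years_mid`) and
were fixed by calibration: among the natural candidates (period start, end,
midpoint; 1–3.5 medication years) only the midpoint/one-plus-two-year
combination is consistent with the published base-case table, so it is the
package default. No real-cost-growth factor is applied in the engine;
general health-cost inflation above CPI is a reporting concern outside a
5-year fixed-price model.

## Parameters and distributions

`ModelParameters` holds 12 probabilities and 6 costs, each a (mean, SD)
pair. For uncertainty propagation each probability gets a **beta**
distribution and each cost a **gamma** distribution by moment matching:

- beta: `alpha = m(m(1−m)/s² − 1)`, `beta = (1−m)(m(1−m)/s² − 1)`,
  feasible iff `s² < m(1−m)`;
- gamma: `shape = m²/s²`, `scale = s²/m`.

Both fits round-trip (mean, SD) in closed form. A zero SD, or a probability
mean sitting on 0 or 1 (the baseline imaging probability is 1 with a nominal
SD of 0.01, for which no beta exists), raises a point-mass signal and the
parameter is simply never sampled. Infeasible moments fail before a PSA
starts, not mid-run.

One printed baseline input is internally inconsistent: the mid-term AWI
reintervention share appears as 0.5 alongside a re-coarctation complement of
0.95. The packaged baseline uses 0.05 — the only value consistent with the
complement rule, and the only one that reproduces the published base case.

## Scenarios

Scenarios are multiplicative edits of a baseline
(`ScenarioSpec`): factors on `p_awi`, both reintervention rates, and both
medication shares, plus an optional success-rate override. Factors apply at
full precision (e.g. 0.9 × 0.091 = 0.0819, not a rounded 8.2 %), results
clamp to [0, 1], and pathway shares and costs are never touched. The four
built-ins are data (`builtin_scenarios()`), expressible in the same
YAML dialect as parameter sets.

## Sensitivity analyses

**Tornado** (`tornado`): every stored parameter is perturbed ×(1±δ), δ = 0.10
by default, one at a time (derived complements move automatically); entries
are ranked by total-cost spread, with ties broken by parameter name for
deterministic output.

**One-way curves** (`one_way_curve`): a named target — the success rate, the
AWI rate, the joint follow-up reintervention rates, the joint medication
shares, or any unit cost — is scaled over a grid of relative multipliers *in
the baseline*; every scenario is then re-derived from the perturbed baseline
via its spec, so scenario multipliers compound with the grid multiplier.
Probabilities clamp at 1, which produces the flat "floor" in the
success-rate curve once the scaled rate reaches certainty.

**PSA** (`run_psa`): n iterations (default 1000), all parameters drawn
independently from their fitted distributions in a fixed order
(probabilities then costs, declaration order), so a seed is portable across
runs and machines. Per iteration one baseline draw is taken and every
scenario is derived from *that* draw (common random numbers); this keeps
per-iteration avoidable costs interpretable and variance-reduced. An
independent per-scenario sampling mode (`coupled=False`) is provided for
comparison — published PSA summaries of this design problem do not pin down
the coupling, and the two modes differ visibly in avoidable-cost variance
though not in means. Summaries are means and percentile (2.5 %, 97.5 %) CIs
with linear interpolation between order statistics. `sd_scale` multiplies
every SD before fitting (the SD-inflation robustness rerun).

## Numerical conventions

- All model arithmetic is double precision and unrounded; rounding to whole
  pounds (half away from zero) happens only at display/report time.
- Avoidable costs are differences of unrounded totals, then rounded — so the
  avoidable row of a report may differ by £1 from the difference of the
  rounded overall cells.
- USD figures are display-only, at a configurable rate (default 1.509).
- Budget impact multiplies the pound-rounded per-patient avoidable cost by
  the annual cohort size, matching how such back-of-envelope figures are
  quoted.

## Synthetic parameter generator

`generate_parameter_set` draws structurally valid random instances:
probability means uniform strictly inside (0, 1), costs uniform in a positive
range, and each SD a uniform fraction of its feasible maximum
(`sqrt(m(1−m))` for probabilities, the mean for costs), so every generated
set admits beta/gamma fits by construction. It emulates the *shape* of the
real inputs — independent parameters with feasible moments — not their
clinical plausibility: generated sets have no correlation structure and no
resemblance to actual CoA event rates, so property tests against them verify
engine algebra (oracle equivalence, monotonicity, round-trips), not clinical
calibration. The packaged baseline is the one clinically meaningful instance.

## Verification

- A brute-force oracle (tests) enumerates every leaf path of the tree with
  its probability and summed cost and must agree with the closed-form engine
  to 1e−9 (relative) on 100 generated parameter sets.
- The packaged baseline reproduces the published base-case table; one
  published cell (baseline mid-term, £5919) is inconsistent with its own
  printed overall by £1, and the engine's £5918 is the value consistent with
  the £16,688 total. Tests therefore require period cells within £1 and all
  totals and avoidable costs exactly.
- PSA checks are property-based: zero variance collapses to the
  deterministic table; means converge to deterministic values (the tree is
  multilinear in independent draws) within 5 standard errors at n = 10⁴;
  SD doubling preserves means and widens every CI; fixed seeds are
  bit-reproducible. Test problem sizes (n = 2000–10⁴) are chosen so the
  statistical assertions have comfortable power while the suite stays quick.

## Limitations

- Costs only — no effectiveness outcomes, so no cost-effectiveness ratios.
- The 5-year horizon excludes late complications (e.g. exercise-induced
  hypertension, late aneurysm) and any costs beyond mid-term follow-up.
- Parameters are sampled independently in PSA; correlated sampling (copulas)
  is out of scope.
- Structural scenario edits (changing the tree shape) are not supported;
  scenarios only modulate parameters.
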