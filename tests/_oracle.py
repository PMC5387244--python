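"""Independent brute-force evaluator of the decision tree.

Enumerates every leaf path of the event tree explicitly — with its path
probability and the sum of costs incurred along it — and computes the expected
cost as sum(prob * cost) over leaves. Kept deliberately naive and structured
as (probability, cost) path products so it shares no code with the
closed-form engine it cross-checks.
"""

from __future__ import annotations

from coarctcost.parameters import DiscountSpec, ModelParameters


def _awi_repair_leaves(params: ModelParameters) -> list[tuple[float, float]]:
    """Leaves below an 'injury occurred' node: percutaneous or surgical repair."""
    return [
        (params.p_awi_percutaneous.mean, params.c_awi_interventional.mean),
        (1.0 - params.p_awi_percutaneous.mean, params.c_awi_surgical.mean),
    ]


def _stent_leaves(params: ModelParameters) -> list[tuple[float, float]]:
    """Leaves of one stenting event: stent cost, then injury or not."""
    leaves = [(1.0 - params.p_awi.mean, params.c_stent.mean)]
    for pr, cost in _awi_repair_leaves(params):
        leaves.append((params.p_awi.mean * pr, params.c_stent.mean + cost))
    return leaves


def initial_leaves(params: ModelParameters) -> list[tuple[float, float]]:
    leaves = []
    ps = params.p_success.mean
    for pr, cost in _stent_leaves(params):
        leaves.append((ps * pr, cost))
    # failure: initial stent cost, then repeat stenting (with injury risk) or surgery
    pf = 1.0 - ps
    prep = params.p_repeat_stent.mean
    for pr, cost in _stent_leaves(params):
        leaves.append((pf * prep * pr, params.c_stent.mean + cost))
    leaves.append((pf * (1.0 - prep), params.c_stent.mean + params.c_surgery.mean))
    return leaves


def followup_leaves(
    params: ModelParameters, period: str, disc: DiscountSpec
) -> list[tuple[float, float]]:
    if period == "short":
        p_img, p_htn, p_reint, p_ra = (
            params.p_imaging_short.mean, params.p_htn_short.mean,
            params.p_reint_short.mean, params.p_reint_awi_short.mean,
        )
        years = disc.htn_years_short
    elif period == "mid":
        p_img, p_htn, p_reint, p_ra = (
            params.p_imaging_mid.mean, params.p_htn_mid.mean,
            params.p_reint_mid.mean, params.p_reint_awi_mid.mean,
        )
        years = disc.htn_years_mid
    else:
        raise ValueError(period)

    # reintervention subtree: none / AWI repair / re-CoA restent (with AWI risk)
    reint: list[tuple[float, float]] = [(1.0 - p_reint, 0.0)]
    for pr, cost in _awi_repair_leaves(params):
        reint.append((p_reint * p_ra * pr, cost))
    for pr, cost in _stent_leaves(params):
        reint.append((p_reint * (1.0 - p_ra) * pr, cost))

    leaves = []
    for pi, ci in ((p_img, params.c_imaging.mean), (1.0 - p_img, 0.0)):
        for ph, ch in ((p_htn, params.c_htn_annual.mean * years), (1.0 - p_htn, 0.0)):
            for pr, cr in reint:
                leaves.append((pi * ph * pr, ci + ch + cr))
    return leaves


def _expect(leaves: list[tuple[float, float]]) -> float:
    assert abs(sum(p for p, _ in leaves) - 1.0) < 1e-9
    return sum(p * c for p, c in leaves)


def oracle_total_cost(params: ModelParameters, disc: DiscountSpec | None = None) -> float:
    """Expected discounted total cost by exhaustive leaf enumeration."""
    if disc is None:
        disc = DiscountSpec()
    d_short = (1.0 + disc.annual_rate) ** -disc.t_short
    d_mid = (1.0 + disc.annual_rate) ** -disc.t_mid
    return (
        _expect(initial_leaves(params))
        + d_short * _expect(followup_leaves(params, "short", disc))
        + d_mid * _expect(followup_leaves(params, "mid", disc))
    )
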