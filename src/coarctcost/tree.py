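"""Closed-form evaluation of the three-period decision tree.

The model follows a cohort of CoA patients through an initial stenting
intervention and two follow-up windows (short-term, 3-18 months; mid-term,
18 months-5 years). Each chance node contributes its probability-weighted
branch costs:

* initial period — successful stenting carries the stent cost plus the
  AWI-risk-weighted repair cost; a failed initial procedure incurs the initial
  stent cost *plus* a second intervention, which is either repeat stenting
  (again with AWI risk) or surgery;
* each follow-up period — an imaging cost, the annual hypertension medication
  cost scaled by the medicated share and the period's year-multiplier, and the
  expected reintervention cost, split between AWI repair and re-coarctation
  restenting (the re-CoA branch is identical to a successful initial stent);
* follow-up totals are discounted as lump sums at the period midpoints; the
  initial period is at t = 0 and undiscounted.

All arithmetic is carried at full precision; rounding to whole pounds is a
display concern (see :mod:`coarctcost.report`).
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import DiscountSpec, ModelParameters

__all__ = [
    "PeriodCosts",
    "AvoidableCost",
    "discount_factor",
    "awi_treatment_cost",
    "stent_event_cost",
    "initial_period_cost",
    "followup_period_cost",
    "total_cost",
    "avoidable_cost",
]

PERIODS = ("short", "mid")


@dataclass(frozen=True)
class PeriodCosts:
    """Expected per-patient cost by period (GBP; follow-up periods discounted)."""

    initial: float
    short_term: float
    mid_term: float

    @property
    def total(self) -> float:
        return self.initial + self.short_term + self.mid_term


@dataclass(frozen=True)
class AvoidableCost:
    """Baseline total minus scenario total, on unrounded values (GBP)."""

    value: float


def discount_factor(annual_rate: float, t_years: float) -> float:
    """Present-value factor (1 + r)^(-t) for a cost incurred t years out."""
    if t_years < 0.0:
        raise ValueError(f"t_years {t_years!r} negative")
    if annual_rate < 0.0:
        raise ValueError(f"annual_rate {annual_rate!r} negative")
    return (1.0 + annual_rate) ** (-t_years)


def awi_treatment_cost(params: ModelParameters) -> float:
    """Expected cost of repairing one aortic wall injury (percutaneous-vs-surgical mix)."""
    p = params.p_awi_percutaneous.mean
    return (
        p * params.c_awi_interventional.mean
        + (1.0 - p) * params.c_awi_surgical.mean
    )


def stent_event_cost(params: ModelParameters) -> float:
    """Cost of one stenting event including its injury risk:
    stent cost + P(AWI) * expected AWI repair cost."""
    return params.c_stent.mean + params.p_awi.mean * awi_treatment_cost(params)


def initial_period_cost(params: ModelParameters) -> float:
    """Expected cost of the initial treatment period (undiscounted).

    A failed initial stent (gradient > 20 mmHg) incurs the initial stent cost
    plus a second intervention: repeat stenting (with AWI risk) or surgery.
    """
    stent_ev = stent_event_cost(params)
    failure_branch = (
        params.c_stent.mean
        + params.p_repeat_stent.mean * stent_ev
        + params.p_surgery.mean * params.c_surgery.mean
    )
    ps = params.p_success.mean
    return ps * stent_ev + (1.0 - ps) * failure_branch


def followup_period_cost(
    params: ModelParameters, period: str, disc: DiscountSpec | None = None
) -> float:
    """Expected *undiscounted* cost of one follow-up period ('short' or 'mid').

    imaging + medication + reintervention, where a reintervention is an AWI
    repair with probability ``p_reint_awi`` and otherwise a re-coarctation
    restent, costed like a successful initial stenting event.
    """
    if period not in PERIODS:
        raise ValueError(f"unknown period {period!r}; expected one of {PERIODS}")
    if disc is None:
        disc = DiscountSpec()
    if period == "short":
        p_imaging, p_htn, p_reint, p_reint_awi = (
            params.p_imaging_short, params.p_htn_short,
            params.p_reint_short, params.p_reint_awi_short,
        )
        htn_years = disc.htn_years_short
    else:
        p_imaging, p_htn, p_reint, p_reint_awi = (
            params.p_imaging_mid, params.p_htn_mid,
            params.p_reint_mid, params.p_reint_awi_mid,
        )
        htn_years = disc.htn_years_mid
    reint_cost = (
        p_reint_awi.mean * awi_treatment_cost(params)
        + (1.0 - p_reint_awi.mean) * stent_event_cost(params)
    )
    return (
        p_imaging.mean * params.c_imaging.mean
        + p_htn.mean * params.c_htn_annual.mean * htn_years
        + p_reint.mean * reint_cost
    )


def total_cost(params: ModelParameters, disc: DiscountSpec | None = None) -> PeriodCosts:
    """Expected per-patient cost of the full 5-year pathway, discounted."""
    if disc is None:
        disc = DiscountSpec()
    return PeriodCosts(
        initial=initial_period_cost(params),
        short_term=followup_period_cost(params, "short", disc)
        * discount_factor(disc.annual_rate, disc.t_short),
        mid_term=followup_period_cost(params, "mid", disc)
        * discount_factor(disc.annual_rate, disc.t_mid),
    )


def avoidable_cost(baseline: PeriodCosts, scenario: PeriodCosts) -> AvoidableCost:
    """Cost avoided by a hypothetical scenario relative to baseline (unrounded)."""
    return AvoidableCost(value=baseline.total - scenario.total)
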