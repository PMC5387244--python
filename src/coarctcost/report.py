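"""Report assembly, budget-impact extrapolation, and currency display.

All model arithmetic is carried at full precision; this module owns the
display conventions — rounding to whole pounds (half away from zero) and the
optional GBP→USD conversion, which is cosmetic and never feeds back into the
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .parameters import DiscountSpec, ModelParameters, ValidationError
from .scenarios import BASELINE_NAME, ScenarioSpec, apply_scenario
from .tree import total_cost

__all__ = ["BudgetImpact", "budget_impact", "to_usd", "build_report", "round_pounds",
           "DEFAULT_USD_RATE"]

#: GBP→USD rate implied by the published cost pairs (December 2015).
DEFAULT_USD_RATE = 1.509


def round_pounds(x: float) -> int:
    """Round to the nearest pound, halves away from zero (display only)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BudgetImpact:
    """Population-level extrapolation of a per-patient avoidable cost."""

    avoidable_per_patient: float  #: GBP per treated patient
    patients_per_year: float
    horizon_years: float = 5.0  #: informational; savings accrue per cohort

    def __post_init__(self) -> None:
        if self.avoidable_per_patient < 0 or self.patients_per_year < 0:
            raise ValidationError("budget-impact inputs must be non-negative")

    @property
    def total_savings(self) -> float:
        return self.avoidable_per_patient * self.patients_per_year


def budget_impact(avoidable_per_patient: float, patients_per_year: float) -> BudgetImpact:
    """Annual-cohort savings: per-patient avoidable cost x patients per year."""
    return BudgetImpact(avoidable_per_patient, patients_per_year)


def to_usd(gbp: float, rate: float = DEFAULT_USD_RATE) -> float:
    """Convert GBP to USD at a fixed exchange rate (display only)."""
    if rate <= 0.0:
        raise ValidationError(f"exchange rate {rate!r} must be positive")
    return gbp * rate


def build_report(
    params: ModelParameters,
    specs: tuple[ScenarioSpec, ...],
    disc: DiscountSpec | None = None,
) -> pd.DataFrame:
    """Assemble the base-case results table: one column per scenario.

    Rows: initial, short_term, mid_term, overall, avoidable_vs_baseline; all
    pound-rounded for display. The avoidable row is the difference of the
    *unrounded* totals (so it need not equal the difference of the rounded
    overall cells).
    """
    if disc is None:
        disc = DiscountSpec()
    columns = {}
    base = total_cost(params, disc)
    columns[BASELINE_NAME] = (base, None)
    for spec in specs:
        pc = total_cost(apply_scenario(params, spec), disc)
        columns[spec.name] = (pc, base.total - pc.total)
    data = {
        name: {
            "initial": round_pounds(pc.initial),
            "short_term": round_pounds(pc.short_term),
            "mid_term": round_pounds(pc.mid_term),
            "overall": round_pounds(pc.total),
            "avoidable_vs_baseline": round_pounds(av) if av is not None else pd.NA,
        }
        for name, (pc, av) in columns.items()
    }
    rows = ["initial", "short_term", "mid_term", "overall", "avoidable_vs_baseline"]
    return pd.DataFrame(data).reindex(rows)
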