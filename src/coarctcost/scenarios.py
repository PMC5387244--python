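"""Hypothetical improvement scenarios: multiplicative edits of a baseline.

Each scenario scales the complication-related probabilities (aortic wall
injury, follow-up reinterventions, hypertension medication) by a fixed factor
and may override the initial treatment success rate. Pathway shares
(repeat-stent vs surgery, percutaneous vs surgical AWI repair) and all unit
costs are left untouched. Scenario probabilities are derived at full
multiplier precision, never from rounded percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import ModelParameters, ProbParam, ValidationError

__all__ = ["ScenarioSpec", "apply_scenario", "builtin_scenarios", "BASELINE_NAME"]

BASELINE_NAME = "Baseline"


@dataclass(frozen=True)
class ScenarioSpec:
    """One hypothetical scenario as multipliers/overrides on a baseline."""

    name: str
    success_override: float | None = None  #: replaces p_success when set
    awi_multiplier: float = 1.0
    reint_multiplier: float = 1.0  #: applies to both follow-up reintervention rates
    htn_multiplier: float = 1.0  #: applies to both medication shares

    def __post_init__(self) -> None:
        for label in ("awi_multiplier", "reint_multiplier", "htn_multiplier"):
            if getattr(self, label) < 0.0:
                raise ValidationError(f"{self.name}: {label} must be >= 0")
        if self.success_override is not None and not 0.0 <= self.success_override <= 1.0:
            raise ValidationError(f"{self.name}: success_override outside [0, 1]")

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "awi_multiplier": self.awi_multiplier,
            "reint_multiplier": self.reint_multiplier,
            "htn_multiplier": self.htn_multiplier,
        }
        if self.success_override is not None:
            d["success_override"] = self.success_override
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(
            name=d["name"],
            success_override=d.get("success_override"),
            awi_multiplier=d.get("awi_multiplier", 1.0),
            reint_multiplier=d.get("reint_multiplier", 1.0),
            htn_multiplier=d.get("htn_multiplier", 1.0),
        )


def _scaled(p: ProbParam, factor: float) -> ProbParam:
    # clamp after multiplying; the SD travels with the parameter unchanged
    return ProbParam(min(1.0, p.mean * factor), p.sd)


def apply_scenario(baseline: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Derive a scenario parameter set from a baseline.

    Multiplies p_awi, both reintervention rates, and both medication shares by
    the spec's factors (clamping to [0, 1]); replaces p_success when an
    override is present. Everything else — pathway shares, imaging, costs —
    is carried over unchanged.
    """
    changes: dict[str, ProbParam] = {
        "p_awi": _scaled(baseline.p_awi, spec.awi_multiplier),
        "p_reint_short": _scaled(baseline.p_reint_short, spec.reint_multiplier),
        "p_reint_mid": _scaled(baseline.p_reint_mid, spec.reint_multiplier),
        "p_htn_short": _scaled(baseline.p_htn_short, spec.htn_multiplier),
        "p_htn_mid": _scaled(baseline.p_htn_mid, spec.htn_multiplier),
    }
    if spec.success_override is not None:
        changes["p_success"] = ProbParam(spec.success_override, baseline.p_success.sd)
    return baseline.replace(**changes)


def builtin_scenarios() -> tuple[ScenarioSpec, ...]:
    """The four built-in improvement scenarios, in reporting order.

    1. complications (AWI, reinterventions) down 10 %;
    2. complications down 25 %, medication down 10 %;
    3. guaranteed initial success, complications down 50 %, medication down 25 %;
    best case — guaranteed success, no complications, no medication.
    """
    return (
        ScenarioSpec("Scenario 1", awi_multiplier=0.9, reint_multiplier=0.9),
        ScenarioSpec(
            "Scenario 2", awi_multiplier=0.75, reint_multiplier=0.75, htn_multiplier=0.9
        ),
        ScenarioSpec(
            "Scenario 3",
            success_override=1.0,
            awi_multiplier=0.5,
            reint_multiplier=0.5,
            htn_multiplier=0.75,
        ),
        ScenarioSpec(
            "Best case",
            success_override=1.0,
            awi_multiplier=0.0,
            reint_multiplier=0.0,
            htn_multiplier=0.0,
        ),
    )
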