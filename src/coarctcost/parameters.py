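"""Model parameters: event probabilities, unit costs, and their sampling distributions.

The cost model of stent repair for coarctation of the aorta (CoA) is driven by a
fixed set of event probabilities (success of the initial stenting, aortic wall
injury, reintervention and medication rates at follow-up) and unit costs
(GBP, 2014 prices). Each parameter carries a point estimate and a standard
deviation; probabilities are given beta distributions and costs gamma
distributions by matching moments, which is how probabilistic sensitivity
analysis propagates parameter uncertainty.

Complementary event shares (e.g. surgery vs. repeat stenting after a failed
initial procedure) are stored once; the complement is always derived, so the
pair cannot drift away from summing to one.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import IO, Iterator, Union

import pandas as pd
import yaml

__all__ = [
    "ProbParam",
    "CostParam",
    "ModelParameters",
    "DiscountSpec",
    "BetaParams",
    "GammaParams",
    "DegenerateDistribution",
    "InfeasibleMomentsError",
    "ConfigError",
    "ValidationError",
    "beta_from_moments",
    "gamma_from_moments",
    "load_parameters",
    "save_parameters",
    "parameter_table",
]

SCHEMA_VERSION = 1

#: ModelParameters fields holding probabilities (beta family), in sampling order.
PROB_FIELDS = (
    "p_success",
    "p_repeat_stent",
    "p_awi",
    "p_awi_percutaneous",
    "p_imaging_short",
    "p_imaging_mid",
    "p_htn_short",
    "p_htn_mid",
    "p_reint_short",
    "p_reint_mid",
    "p_reint_awi_short",
    "p_reint_awi_mid",
)

#: ModelParameters fields holding unit costs (gamma family), in sampling order.
COST_FIELDS = (
    "c_stent",
    "c_surgery",
    "c_awi_interventional",
    "c_awi_surgical",
    "c_imaging",
    "c_htn_annual",
)


class ConfigError(ValueError):
    """A parameter configuration is structurally invalid (missing/unknown keys)."""


class ValidationError(ValueError):
    """A parameter value violates its domain (probability range, sign, ...)."""


class DegenerateDistribution(Exception):
    """Signal that a (mean, sd) pair describes a point mass, not a proper
    distribution: sd is zero, or a probability mean sits on the boundary.

    Callers treat the parameter as fixed at its mean (it is never sampled)."""


class InfeasibleMomentsError(ValueError):
    """No beta distribution has the requested mean and SD (sd^2 >= mean*(1-mean))."""


@dataclass(frozen=True)
class ProbParam:
    """An event probability with its uncertainty (dimensionless, in [0, 1])."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean <= 1.0:
            raise ValidationError(f"probability mean {self.mean!r} outside [0, 1]")
        if self.sd < 0.0:
            raise ValidationError(f"probability sd {self.sd!r} negative")

    @property
    def complement(self) -> "ProbParam":
        """The complementary event share, same SD (the pair moves together)."""
        return ProbParam(1.0 - self.mean, self.sd)


@dataclass(frozen=True)
class CostParam:
    """A unit cost with its uncertainty (GBP, 2014 prices, non-negative)."""

    mean: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean < 0.0:
            raise ValidationError(f"cost mean {self.mean!r} negative")
        if self.sd < 0.0:
            raise ValidationError(f"cost sd {self.sd!r} negative")


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter set for one instance of the CoA stenting cost model.

    Probabilities printed alongside their complements in the source tables are
    stored once; derived complements are exposed as properties.
    """

    p_success: ProbParam  #: initial stenting success (gradient <= 20 mmHg)
    p_repeat_stent: ProbParam  #: second intervention is repeat stenting (vs surgery)
    p_awi: ProbParam  #: aortic wall injury after any stenting event
    p_awi_percutaneous: ProbParam  #: AWI repaired percutaneously (vs surgically)
    p_imaging_short: ProbParam
    p_imaging_mid: ProbParam
    p_htn_short: ProbParam  #: on anti-hypertensive medication, short-term
    p_htn_mid: ProbParam
    p_reint_short: ProbParam  #: any reintervention during short-term follow-up
    p_reint_mid: ProbParam
    p_reint_awi_short: ProbParam  #: share of reinterventions due to AWI (vs re-CoA)
    p_reint_awi_mid: ProbParam
    c_stent: CostParam
    c_surgery: CostParam
    c_awi_interventional: CostParam
    c_awi_surgical: CostParam
    c_imaging: CostParam
    c_htn_annual: CostParam  #: medication + annual GP check-up, per year

    # Derived complements — never stored, never configured.
    @property
    def p_surgery(self) -> ProbParam:
        return self.p_repeat_stent.complement

    @property
    def p_awi_surgical(self) -> ProbParam:
        return self.p_awi_percutaneous.complement

    @property
    def p_reint_recoa_short(self) -> ProbParam:
        return self.p_reint_awi_short.complement

    @property
    def p_reint_recoa_mid(self) -> ProbParam:
        return self.p_reint_awi_mid.complement

    def replace(self, **changes: Union[ProbParam, CostParam]) -> "ModelParameters":
        return dataclasses.replace(self, **changes)

    def items(self) -> Iterator[tuple[str, Union[ProbParam, CostParam]]]:
        for f in fields(self):
            yield f.name, getattr(self, f.name)


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting and period-timing conventions.

    Follow-up costs are discounted as a lump sum at the period midpoint:
    0.875 y for short-term (3-18 months) and 3.25 y for mid-term (18-60 months),
    at the standard NHS rate of 3.5 % per year. The annual hypertension cost
    accrues once in the short-term period and twice in the mid-term period.
    """

    annual_rate: float = 0.035
    t_short: float = 0.875
    t_mid: float = 3.25
    htn_years_short: float = 1.0
    htn_years_mid: float = 2.0

    def __post_init__(self) -> None:
        if self.annual_rate < 0.0:
            raise ValidationError(f"annual_rate {self.annual_rate!r} negative")
        if not self.t_short < self.t_mid:
            raise ValidationError("t_short must precede t_mid")
        if self.htn_years_short < 0.0 or self.htn_years_mid < 0.0:
            raise ValidationError("hypertension year-multipliers must be >= 0")


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution fitted by moment matching."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0.0 or self.beta <= 0.0:
            raise ValidationError("beta shapes must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta
        return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))


@dataclass(frozen=True)
class GammaParams:
    """Shape/scale parameters of a gamma distribution fitted by moment matching."""

    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0.0 or self.scale <= 0.0:
            raise ValidationError("gamma shape and scale must be positive")

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def sd(self) -> float:
        return math.sqrt(self.shape) * self.scale


def beta_from_moments(mean: float, sd: float) -> BetaParams:
    """Method-of-moments beta fit for a probability.

    alpha = m*(m*(1-m)/s^2 - 1), beta = (1-m)*(m*(1-m)/s^2 - 1).

    Raises
    ------
    DegenerateDistribution
        If the mean is 0 or 1, or sd is 0 — a point mass, not a beta.
    InfeasibleMomentsError
        If sd^2 >= mean*(1-mean): no beta distribution has these moments.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValidationError(f"probability mean {mean!r} outside [0, 1]")
    if sd < 0.0:
        raise ValidationError(f"sd {sd!r} negative")
    if sd == 0.0 or mean in (0.0, 1.0):
        raise DegenerateDistribution(f"point mass at {mean}")
    var = sd * sd
    limit = mean * (1.0 - mean)
    if var >= limit:
        raise InfeasibleMomentsError(
            f"sd^2 = {var:g} >= mean*(1-mean) = {limit:g}: no beta has these moments"
        )
    nu = limit / var - 1.0  # pseudo sample size alpha+beta
    return BetaParams(alpha=mean * nu, beta=(1.0 - mean) * nu)


def gamma_from_moments(mean: float, sd: float) -> GammaParams:
    """Method-of-moments gamma fit for a cost: shape = m^2/s^2, scale = s^2/m."""
    if mean <= 0.0:
        raise ValidationError(f"cost mean {mean!r} must be positive for a gamma fit")
    if sd < 0.0:
        raise ValidationError(f"sd {sd!r} negative")
    if sd == 0.0:
        raise DegenerateDistribution(f"point mass at {mean}")
    return GammaParams(shape=(mean / sd) ** 2, scale=sd * sd / mean)


def _field_family(name: str) -> str:
    return "beta" if name in PROB_FIELDS else "gamma"


_ALL_FIELDS = PROB_FIELDS + COST_FIELDS


def load_parameters(source: Union[str, Path, IO[str], dict]) -> ModelParameters:
    """Load and validate a parameter set from YAML (path, stream, or mapping).

    The config is a flat mapping: one ``{mean, sd}`` entry per stored parameter,
    plus ``schema_version``. Unknown keys are rejected; values are taken
    verbatim (no rounding).
    """
    if isinstance(source, dict):
        raw = dict(source)
    elif isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(source)
    if not isinstance(raw, dict):
        raise ConfigError("parameter config must be a mapping")
    raw.pop("schema_version", None)

    unknown = sorted(set(raw) - set(_ALL_FIELDS))
    if unknown:
        raise ConfigError(f"unknown parameter keys: {', '.join(unknown)}")
    missing = sorted(set(_ALL_FIELDS) - set(raw))
    if missing:
        raise ConfigError(f"missing parameter keys: {', '.join(missing)}")

    kwargs: dict[str, Union[ProbParam, CostParam]] = {}
    for name in _ALL_FIELDS:
        entry = raw[name]
        if not isinstance(entry, dict) or "mean" not in entry:
            raise ConfigError(f"entry for {name} must be a mapping with 'mean' (and 'sd')")
        extra = set(entry) - {"mean", "sd"}
        if extra:
            raise ConfigError(f"entry for {name} has unknown keys: {sorted(extra)}")
        mean = entry["mean"]
        sd = entry.get("sd", 0.0)
        if not isinstance(mean, (int, float)) or not isinstance(sd, (int, float)):
            raise ConfigError(f"entry for {name} must hold numeric mean/sd")
        cls = ProbParam if name in PROB_FIELDS else CostParam
        try:
            kwargs[name] = cls(float(mean), float(sd))
        except ValidationError as exc:
            raise ValidationError(f"{name}: {exc}") from None
    return ModelParameters(**kwargs)


def save_parameters(params: ModelParameters, destination: Union[str, Path, IO[str]]) -> None:
    """Write a parameter set as YAML; ``load_parameters`` round-trips it exactly.

    Only stored parameters are written — complements are never persisted.
    """
    doc: dict = {"schema_version": SCHEMA_VERSION}
    for name, p in params.items():
        doc[name] = {"mean": p.mean, "sd": p.sd}
    text = yaml.safe_dump(doc, sort_keys=False)
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        destination.write(text)


def parameter_table(params: ModelParameters) -> pd.DataFrame:
    """The parameter set as a tidy table (name, mean, sd, family) for CSV export."""
    rows = [
        {"name": name, "mean": p.mean, "sd": p.sd, "family": _field_family(name)}
        for name, p in params.items()
    ]
    return pd.DataFrame(rows, columns=["name", "mean", "sd", "family"])
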