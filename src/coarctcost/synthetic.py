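"""Synthetic parameter sets: the packaged baseline and random valid instances.

`baseline_2014` loads the published 2013-14 NHS-reference-cost baseline that
every headline result is computed from. `generate_parameter_set` draws random
but structurally valid parameter sets — probabilities in (0, 1) with SDs
feasible for a beta moment fit, positive costs — so every downstream stage
(tree evaluation, scenarios, sensitivity analyses, PSA) can be property-tested
without external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .parameters import (
    COST_FIELDS,
    PROB_FIELDS,
    CostParam,
    ModelParameters,
    ProbParam,
    load_parameters,
)

__all__ = ["GeneratorSpec", "generate_parameter_set", "baseline_2014"]


def baseline_2014() -> ModelParameters:
    """The packaged baseline parameter set (GBP, 2014 prices)."""
    ref = resources.files("coarctcost.data") / "baseline_2014.yaml"
    with resources.as_file(ref) as path:
        return load_parameters(path)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ranges for random parameter generation.

    Probability means are drawn uniformly inside ``prob_range`` (kept strictly
    inside (0, 1) so a beta fit always exists); cost means uniformly inside
    ``cost_range``; each SD is a uniform fraction — ``sd_fraction_range`` — of
    the largest SD feasible for that parameter (sqrt(m(1-m)) for
    probabilities, the mean itself for costs).
    """

    seed: int = 0
    prob_range: tuple[float, float] = (0.01, 0.99)
    cost_range: tuple[float, float] = (10.0, 20000.0)
    sd_fraction_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        lo, hi = self.prob_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("prob_range must lie strictly inside (0, 1)")
        lo, hi = self.cost_range
        if not 0.0 < lo <= hi:
            raise ValueError("cost_range must be positive")
        lo, hi = self.sd_fraction_range
        if not 0.0 <= lo <= hi < 1.0:
            raise ValueError("sd_fraction_range must lie within [0, 1)")


def generate_parameter_set(spec: GeneratorSpec | None = None) -> ModelParameters:
    """Draw one random, fully valid ModelParameters (deterministic per seed)."""
    if spec is None:
        spec = GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    kwargs: dict[str, ProbParam | CostParam] = {}
    for name in PROB_FIELDS:
        m = float(rng.uniform(*spec.prob_range))
        # sd < sqrt(m(1-m)) guarantees a feasible beta moment fit
        sd = float(rng.uniform(*spec.sd_fraction_range) * np.sqrt(m * (1.0 - m)))
        kwargs[name] = ProbParam(m, sd)
    for name in COST_FIELDS:
        m = float(rng.uniform(*spec.cost_range))
        sd = float(rng.uniform(*spec.sd_fraction_range) * m)
        kwargs[name] = CostParam(m, sd)
    return ModelParameters(**kwargs)
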