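"""Probabilistic sensitivity analysis (PSA): Monte-Carlo uncertainty propagation.

Every probability is sampled from its moment-matched beta distribution and
every cost from its moment-matched gamma distribution, so draws respect the
parameter domains by construction. Per iteration one baseline draw is taken
and every scenario is derived from *that* draw via its multipliers (common
random numbers), keeping per-iteration avoidable costs interpretable and
variance-reduced; an independent per-scenario sampling mode is available via
``coupled=False``. Point-mass parameters (zero SD, or a probability pinned at
0 or 1, such as the imaging rate of 1) are never sampled.

Sampling order is fixed — probabilities then costs, in declaration order — so
a given seed yields the same draws across runs and machines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import (
    COST_FIELDS,
    PROB_FIELDS,
    BetaParams,
    CostParam,
    DegenerateDistribution,
    DiscountSpec,
    GammaParams,
    InfeasibleMomentsError,
    ModelParameters,
    ProbParam,
    beta_from_moments,
    gamma_from_moments,
)
from .scenarios import BASELINE_NAME, ScenarioSpec, apply_scenario
from .tree import total_cost

__all__ = ["PSAResult", "fit_distributions", "sample_parameters", "run_psa", "summarize_psa"]

CI_PERCENTILES = (2.5, 97.5)


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration totals and avoidable costs from one PSA run.

    ``totals`` has one column per scenario (baseline first); ``avoidable`` has
    one column per non-baseline scenario, each the per-iteration difference
    between the baseline column and that scenario's column.
    """

    n_iterations: int
    seed: int
    sd_scale: float
    scenario_names: tuple[str, ...]
    totals: np.ndarray  #: shape (n_iterations, n_scenarios)
    avoidable: np.ndarray  #: shape (n_iterations, n_scenarios - 1)


def fit_distributions(
    params: ModelParameters, sd_scale: float = 1.0
) -> dict[str, BetaParams | GammaParams | None]:
    """Moment-fit every parameter's sampling distribution up front.

    Returns ``None`` for point masses. Raises :class:`InfeasibleMomentsError`
    immediately if any probability's (mean, scaled SD) admits no beta fit, so
    a PSA cannot fail mid-run.
    """
    if sd_scale <= 0.0:
        raise ValueError(f"sd_scale {sd_scale!r} must be > 0")
    fits: dict[str, BetaParams | GammaParams | None] = {}
    for name, p in params.items():
        fit_fn = beta_from_moments if name in PROB_FIELDS else gamma_from_moments
        try:
            fits[name] = fit_fn(p.mean, p.sd * sd_scale)
        except DegenerateDistribution:
            fits[name] = None
        except InfeasibleMomentsError as exc:
            raise InfeasibleMomentsError(f"{name}: {exc}") from None
    return fits


def _draw(
    fits: dict[str, BetaParams | GammaParams | None],
    params: ModelParameters,
    rng: np.random.Generator,
) -> ModelParameters:
    changes: dict[str, ProbParam | CostParam] = {}
    for name in PROB_FIELDS:
        fit = fits[name]
        mean = getattr(params, name).mean if fit is None else rng.beta(fit.alpha, fit.beta)
        changes[name] = ProbParam(float(mean), 0.0)
    for name in COST_FIELDS:
        fit = fits[name]
        mean = getattr(params, name).mean if fit is None else rng.gamma(fit.shape, fit.scale)
        changes[name] = CostParam(float(mean), 0.0)
    return params.replace(**changes)


def sample_parameters(
    params: ModelParameters,
    rng: np.random.Generator,
    sd_scale: float = 1.0,
) -> ModelParameters:
    """One joint draw of all parameters (independent across parameters).

    Returned parameters carry the sampled values as means with zero SD — a
    realized draw is a point in parameter space.
    """
    return _draw(fit_distributions(params, sd_scale), params, rng)


def run_psa(
    params: ModelParameters,
    specs: tuple[ScenarioSpec, ...],
    disc: DiscountSpec | None = None,
    n: int = 1000,
    seed: int = 0,
    sd_scale: float = 1.0,
    coupled: bool = True,
) -> PSAResult:
    """Run ``n`` Monte-Carlo iterations of the model over all scenarios.

    With ``coupled=True`` (default) each iteration takes a single baseline
    draw and derives every scenario from it. With ``coupled=False`` every
    scenario column gets its own independent draw before its spec is applied.
    ``sd_scale`` multiplies every SD before fitting (the SD-inflation rerun).
    """
    if not isinstance(seed, (int, np.integer)) or isinstance(seed, bool):
        raise TypeError(f"seed must be an integer, got {seed!r}")
    if n < 1:
        raise ValueError(f"n {n!r} must be >= 1")
    if disc is None:
        disc = DiscountSpec()
    fits = fit_distributions(params, sd_scale)
    rng = np.random.default_rng(int(seed))
    names = (BASELINE_NAME,) + tuple(s.name for s in specs)
    totals = np.empty((n, len(names)))
    for i in range(n):
        if coupled:
            draw = _draw(fits, params, rng)
            totals[i, 0] = total_cost(draw, disc).total
            for j, spec in enumerate(specs, start=1):
                totals[i, j] = total_cost(apply_scenario(draw, spec), disc).total
        else:
            totals[i, 0] = total_cost(_draw(fits, params, rng), disc).total
            for j, spec in enumerate(specs, start=1):
                draw = _draw(fits, params, rng)
                totals[i, j] = total_cost(apply_scenario(draw, spec), disc).total
    avoidable = totals[:, :1] - totals[:, 1:]
    return PSAResult(
        n_iterations=n,
        seed=int(seed),
        sd_scale=sd_scale,
        scenario_names=names,
        totals=totals,
        avoidable=avoidable,
    )


def summarize_psa(result: PSAResult) -> pd.DataFrame:
    """Mean and percentile 95 % CI per scenario, for totals and avoidable costs.

    Percentiles use linear interpolation between order statistics. Values are
    unrounded; pound-rounding is for display only.
    """
    lo, hi = CI_PERCENTILES
    rows = []
    for j, name in enumerate(result.scenario_names):
        col = result.totals[:, j]
        row = {
            "scenario": name,
            "mean_total": float(col.mean()),
            "total_ci_low": float(np.percentile(col, lo)),
            "total_ci_high": float(np.percentile(col, hi)),
        }
        if j > 0:
            av = result.avoidable[:, j - 1]
            row.update(
                mean_avoidable=float(av.mean()),
                avoidable_ci_low=float(np.percentile(av, lo)),
                avoidable_ci_high=float(np.percentile(av, hi)),
            )
        else:
            row.update(
                mean_avoidable=np.nan, avoidable_ci_low=np.nan, avoidable_ci_high=np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def iterations_table(result: PSAResult) -> pd.DataFrame:
    """Per-iteration long table (iteration, scenario, total, avoidable)."""
    records = []
    for j, name in enumerate(result.scenario_names):
        for i in range(result.n_iterations):
            records.append(
                {
                    "iteration": i,
                    "scenario": name,
                    "total": result.totals[i, j],
                    "avoidable": result.avoidable[i, j - 1] if j > 0 else np.nan,
                }
            )
    return pd.DataFrame(records)
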