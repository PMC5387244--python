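"""Deterministic sensitivity analysis: tornado ranking and one-way curves.

The tornado perturbs every stored parameter one at a time by +/-10 % (derived
complements move automatically) and ranks parameters by the spread of the
total cost. One-way curves scale a chosen input over a grid of relative
multipliers in the baseline and re-derive every scenario from that perturbed
baseline, tracing how total costs — and hence avoidable costs — respond.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .parameters import (
    COST_FIELDS,
    PROB_FIELDS,
    CostParam,
    DiscountSpec,
    ModelParameters,
    ProbParam,
)
from .scenarios import BASELINE_NAME, ScenarioSpec, apply_scenario
from .tree import total_cost

__all__ = [
    "TornadoEntry",
    "OneWayCurve",
    "ONE_WAY_TARGETS",
    "tornado",
    "one_way_curve",
    "tornado_table",
    "one_way_table",
]

#: Named probability targets for one-way curves; "reintervention" and "htn"
#: move their short- and mid-term rates jointly. Any cost field is also a
#: valid target.
ONE_WAY_TARGETS = {
    "success": ("p_success",),
    "awi": ("p_awi",),
    "reintervention": ("p_reint_short", "p_reint_mid"),
    "htn": ("p_htn_short", "p_htn_mid"),
}


@dataclass(frozen=True)
class TornadoEntry:
    """One parameter's low/high total-cost excursion under the +/- perturbation."""

    parameter: str
    low_total: float
    high_total: float

    @property
    def spread(self) -> float:
        return abs(self.high_total - self.low_total)


@dataclass(frozen=True)
class OneWayCurve:
    """Total cost per scenario along a grid of relative multipliers of one input."""

    parameter: str
    grid: tuple[float, ...]
    scenario_names: tuple[str, ...]  #: Baseline first, then the scenarios
    totals: tuple[tuple[float, ...], ...]  #: totals[i][j]: grid point i, scenario j


def _perturb(params: ModelParameters, name: str, factor: float) -> ModelParameters:
    p = getattr(params, name)
    if name in PROB_FIELDS:
        return params.replace(**{name: ProbParam(min(1.0, max(0.0, p.mean * factor)), p.sd)})
    return params.replace(**{name: CostParam(p.mean * factor, p.sd)})


def tornado(
    params: ModelParameters,
    disc: DiscountSpec | None = None,
    delta: float = 0.10,
) -> tuple[TornadoEntry, ...]:
    """Rank all stored inputs by total-cost spread under a +/- delta perturbation.

    Entries are sorted by spread descending; ties break on parameter name so
    the ordering is deterministic.
    """
    if delta < 0.0:
        raise ValueError(f"delta {delta!r} must be >= 0")
    if disc is None:
        disc = DiscountSpec()
    entries = []
    for name in PROB_FIELDS + COST_FIELDS:
        low = total_cost(_perturb(params, name, 1.0 - delta), disc).total
        high = total_cost(_perturb(params, name, 1.0 + delta), disc).total
        entries.append(TornadoEntry(name, low, high))
    return tuple(sorted(entries, key=lambda e: (-e.spread, e.parameter)))


def one_way_curve(
    params: ModelParameters,
    target: str,
    grid: list[float] | tuple[float, ...],
    specs: tuple[ScenarioSpec, ...],
    disc: DiscountSpec | None = None,
) -> OneWayCurve:
    """Trace scenario totals while scaling one baseline input over ``grid``.

    ``target`` is a named probability group from :data:`ONE_WAY_TARGETS` or any
    cost field. At each grid point the multiplier is applied to the *baseline*;
    every scenario is then re-derived from that modified baseline via its spec,
    so scenario multipliers compound with the grid multiplier. Probabilities
    clamp at 1 (curves for the success rate flatten once the override floor
    is reached).
    """
    if target in ONE_WAY_TARGETS:
        varied = ONE_WAY_TARGETS[target]
    elif target in COST_FIELDS:
        varied = (target,)
    else:
        raise ValueError(
            f"unknown one-way target {target!r}; expected one of "
            f"{sorted(ONE_WAY_TARGETS) + list(COST_FIELDS)}"
        )
    grid = tuple(float(g) for g in grid)
    if any(g < 0.0 for g in grid):
        raise ValueError("grid multipliers must be >= 0")
    if list(grid) != sorted(set(grid)):
        raise ValueError("grid must be strictly increasing")
    if disc is None:
        disc = DiscountSpec()

    names = (BASELINE_NAME,) + tuple(s.name for s in specs)
    rows = []
    for g in grid:
        perturbed = params
        for name in varied:
            perturbed = _perturb(perturbed, name, g)
        totals = [total_cost(perturbed, disc).total]
        totals += [total_cost(apply_scenario(perturbed, s), disc).total for s in specs]
        rows.append(tuple(totals))
    return OneWayCurve(parameter=target, grid=grid, scenario_names=names, totals=tuple(rows))


def tornado_table(entries: tuple[TornadoEntry, ...]) -> pd.DataFrame:
    """Tornado results as a table (parameter, low, high, spread), for CSV export."""
    return pd.DataFrame(
        [
            {"parameter": e.parameter, "low": e.low_total, "high": e.high_total,
             "spread": e.spread}
            for e in entries
        ]
    )


def one_way_table(curve: OneWayCurve) -> pd.DataFrame:
    """One-way curve in long format (parameter, multiplier, scenario, total)."""
    records = [
        {
            "parameter": curve.parameter,
            "multiplier": g,
            "scenario": name,
            "total": curve.totals[i][j],
        }
        for i, g in enumerate(curve.grid)
        for j, name in enumerate(curve.scenario_names)
    ]
    return pd.DataFrame(records)
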