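"""Cost-effectiveness assembly: frontier, ICERs, dominance, threshold verdicts.

Strategies are ordered from least to most costly; the incremental
cost-effectiveness ratio (ICER) of each surviving strategy is the ratio of its
incremental cost to its incremental QALYs against the previous strategy on the
efficiency frontier. Strictly dominated strategies (at least as costly, no more
effective) and extended-dominated strategies (ICER exceeding that of a more
effective alternative) are removed before frontier ICERs are read off; both
labels collapse to the single word "Dominated" in report output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .costing import CostBreakdown, costing_for, discounted_costs
from .markov import MarkovTrace, discounted_qalys, run_cohort_trace
from .parameters import CETRange, ParameterSet

__all__ = [
    "StrategyResult",
    "CEAEntry",
    "CEATable",
    "evaluate_strategy",
    "evaluate_all",
    "compute_icers",
    "pairwise_icer",
    "cet_verdict",
    "scenario_without",
    "cea_frame",
]


@dataclass(frozen=True)
class StrategyResult:
    """Discounted lifetime cost and QALYs for one strategy."""

    regimen: str
    total_cost: float
    total_qalys: float
    cost_breakdown: CostBreakdown | None = None
    trace: MarkovTrace | None = None

    def __post_init__(self) -> None:
        if self.total_cost < 0 or self.total_qalys < 0:
            raise ValueError("costs and QALYs must be non-negative")


def evaluate_strategy(params: ParameterSet, regimen: str) -> StrategyResult:
    """Run trace, QALY and cost accumulation for one regimen under one parameter set."""
    if regimen not in params.transition_schedules:
        raise KeyError(
            f"unknown regimen {regimen!r}; have {list(params.transition_schedules)}"
        )
    trace = run_cohort_trace(params.transition_schedules[regimen], params.settings)
    qalys = discounted_qalys(trace, params.utilities, params.settings)
    breakdown = discounted_costs(trace, costing_for(params, regimen), params.settings)
    return StrategyResult(
        regimen=regimen,
        total_cost=breakdown.total,
        total_qalys=qalys,
        cost_breakdown=breakdown,
        trace=trace,
    )


def evaluate_all(params: ParameterSet, regimens=None) -> list[StrategyResult]:
    return [evaluate_strategy(params, r) for r in (regimens or params.regimens)]


@dataclass
class CEAEntry:
    regimen: str
    total_cost: float
    total_qalys: float
    incremental_cost: float | None = None
    incremental_qalys: float | None = None
    icer: float | None = None
    comparator: str | None = None
    dominance: str = "none"  # none | strict | extended
    duplicate_of: str | None = None

    @property
    def on_frontier(self) -> bool:
        return self.dominance == "none"

    @property
    def icer_label(self) -> str:
        if self.dominance != "none":
            return "Dominated"
        if self.icer is None:
            return ""
        return f"{self.icer:.0f}"


@dataclass
class CEATable:
    """Strategies sorted by ascending cost, with frontier ICERs and dominance labels."""

    entries: list[CEAEntry]

    @property
    def frontier(self) -> list[CEAEntry]:
        return [e for e in self.entries if e.on_frontier]

    def entry(self, regimen: str) -> CEAEntry:
        for e in self.entries:
            if e.regimen == regimen:
                return e
        raise KeyError(regimen)

    def frontier_icer(self, regimen: str) -> float | None:
        """The regimen's ICER on the frontier, or None if it is the cheapest strategy.

        Raises ValueError for a dominated strategy, which carries no frontier ICER.
        """
        e = self.entry(regimen)
        if not e.on_frontier:
            raise ValueError(f"{regimen} is dominated and has no frontier ICER")
        return e.icer


def pairwise_icer(cheaper: StrategyResult, costlier: StrategyResult) -> float:
    """Head-to-head ICER of ``costlier`` vs ``cheaper`` (no frontier logic)."""
    dq = costlier.total_qalys - cheaper.total_qalys
    dc = costlier.total_cost - cheaper.total_cost
    if dq == 0:
        return float("inf") if dc > 0 else 0.0
    return dc / dq


def compute_icers(results: list[StrategyResult]) -> CEATable:
    """Build the efficiency frontier with strict and extended dominance labels.

    Ties in cost are ordered by QALYs descending; exact cost-and-QALY ties keep
    the first strategy (input order) and flag the rest as duplicates (strictly
    dominated for frontier purposes).
    """
    if len(results) < 2:
        raise ValueError("need at least 2 strategies")
    ids = [r.regimen for r in results]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate regimen ids in {ids}")

    order = sorted(
        range(len(results)),
        key=lambda i: (results[i].total_cost, -results[i].total_qalys, i),
    )
    entries = [
        CEAEntry(results[i].regimen, results[i].total_cost, results[i].total_qalys)
        for i in order
    ]

    # strict dominance (incl. equal-cost, equal-QALY duplicates beyond the first)
    for a, b in itertools.combinations(range(len(entries)), 2):
        lo, hi = entries[a], entries[b]  # lo is cheaper or tie-preferred
        if hi.dominance != "none":
            continue
        if lo.total_cost <= hi.total_cost and lo.total_qalys >= hi.total_qalys:
            hi.dominance = "strict"
            if (
                lo.total_cost == hi.total_cost
                and lo.total_qalys == hi.total_qalys
            ):
                hi.duplicate_of = lo.regimen

    # extended dominance: remove strategies whose ICER exceeds that of a more
    # effective strategy, recomputing frontier ICERs after each removal
    while True:
        frontier = [e for e in entries if e.dominance == "none"]
        icers: list[float | None] = [None]
        for prev, cur in zip(frontier, frontier[1:]):
            dq = cur.total_qalys - prev.total_qalys
            dc = cur.total_cost - prev.total_cost
            icers.append(0.0 if dq > 0 and dc <= 0 else dc / dq)
        removed = False
        for k in range(1, len(frontier) - 1):
            if icers[k] is not None and icers[k + 1] is not None and icers[k] > icers[k + 1]:
                frontier[k].dominance = "extended"
                removed = True
                break
        if not removed:
            break

    # final frontier increments
    frontier = [e for e in entries if e.dominance == "none"]
    for prev, cur in zip(frontier, frontier[1:]):
        cur.incremental_cost = cur.total_cost - prev.total_cost
        cur.incremental_qalys = cur.total_qalys - prev.total_qalys
        cur.comparator = prev.regimen
        if cur.incremental_qalys > 0 and cur.incremental_cost <= 0:
            cur.icer = 0.0
        else:
            cur.icer = cur.incremental_cost / cur.incremental_qalys
    return CEATable(entries)


def cet_verdict(
    table: CEATable, cets: CETRange
) -> dict[str, dict[str, bool]]:
    """Cost-effectiveness verdict per strategy per threshold.

    A frontier strategy is cost-effective at a threshold iff its ICER does not
    exceed it (the cheapest, reference strategy counts as cost-effective);
    dominated strategies are never cost-effective.
    """
    thresholds = {
        "low_cet": cets.low_cet,
        "primary_cet": cets.primary_cet,
        "high_cet": cets.high_cet,
    }
    verdicts: dict[str, dict[str, bool]] = {}
    for e in table.entries:
        verdicts[e.regimen] = {
            name: e.on_frontier and (e.icer is None or e.icer <= cet)
            for name, cet in thresholds.items()
        }
    return verdicts


def scenario_without(params: ParameterSet, excluded: str) -> CEATable:
    """Full CEA on the strategy set with one regimen excluded."""
    if excluded not in params.transition_schedules:
        raise KeyError(f"regimen {excluded!r} not in the strategy set")
    remaining = [r for r in params.regimens if r != excluded]
    if len(remaining) < 2:
        raise ValueError("excluding that regimen leaves fewer than 2 strategies")
    return compute_icers(evaluate_all(params, remaining))


def cea_frame(table: CEATable, verdicts: dict | None = None) -> pd.DataFrame:
    """Report mirroring the published base-case layout, plus dominance and verdicts."""
    rows = []
    for e in table.entries:
        row = {
            "strategy": e.regimen,
            "total_cost": e.total_cost,
            "total_qalys": e.total_qalys,
            "incremental_cost": e.incremental_cost,
            "incremental_qalys": e.incremental_qalys,
            "icer": e.icer,
            "icer_label": e.icer_label,
            "dominance": e.dominance,
            "comparator": e.comparator,
        }
        if verdicts:
            for name, ok in verdicts[e.regimen].items():
                row[f"cost_effective_at_{name}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)
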