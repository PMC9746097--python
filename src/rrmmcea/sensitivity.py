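"""Deterministic sensitivity analysis and price-threshold search.

One-way analysis re-runs the full cost-effectiveness comparison twice per
parameter (a low and a high bound) with everything else held at base case,
producing tornado-ready output ordered by ICER range width. The threshold
analysis bisects on a drug-price multiplier until the regimen's frontier ICER
meets a willingness-to-pay threshold, recomputing the whole frontier at every
iterate so the comparator may change as dominance shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cea import CEATable, compute_icers, evaluate_all
from .parameters import ParameterSet, scale_parameter, set_parameter

__all__ = [
    "Bound",
    "OneWayAnalysis",
    "DSARow",
    "DSAResult",
    "ThresholdResult",
    "default_dsa_spec",
    "run_one_way",
    "tornado_table",
    "threshold_price",
    "dsa_frame",
    "DRUG_PRICE_FIELD",
]

#: which unit-cost field is "the drug price" of each regimen (for the
#: lenalidomide arm the threshold question concerns lenalidomide itself)
DRUG_PRICE_FIELD = {
    "DEX": "unit_costs.price_dex_40mg",
    "BORT": "unit_costs.price_bort_per_mg",
    "LEN/DEX": "unit_costs.price_len_25mg",
}


@dataclass(frozen=True)
class Bound:
    """One end of a one-way variation: a multiplier on, or replacement of, the base value."""

    mode: str  # "multiplier" | "value"
    amount: float

    def __post_init__(self) -> None:
        if self.mode not in ("multiplier", "value"):
            raise ValueError("mode must be 'multiplier' or 'value'")
        if self.mode == "multiplier" and self.amount <= 0:
            raise ValueError("multipliers must be > 0")

    def apply(self, params: ParameterSet, targets: tuple[str, ...]) -> ParameterSet:
        out = params
        for t in targets:
            out = (
                scale_parameter(out, t, self.amount)
                if self.mode == "multiplier"
                else set_parameter(out, t, self.amount)
            )
        return out


@dataclass(frozen=True)
class OneWayAnalysis:
    """A named one-way variation applied jointly to one or more parameter paths."""

    name: str
    targets: tuple[str, ...]
    low: Bound
    high: Bound

    def __post_init__(self) -> None:
        if (self.low.mode, self.low.amount) == (self.high.mode, self.high.amount):
            raise ValueError(f"{self.name}: low and high bounds are identical")


def default_dsa_spec(params: ParameterSet) -> list[OneWayAnalysis]:
    """The published one-way analysis set.

    Discount rates vary over 0-10% (HTA guideline); outpatient/inpatient costs
    and transition probabilities by +/-50% (probabilities capped at 1); drug
    prices by +/-40% (literature-based); the pre-progression utilities up to
    the perfect-health ceiling of 1 (lower bound -50%).
    """
    analyses = [
        OneWayAnalysis(
            "discount_rate",
            (
                "settings.annual_discount_rate_costs",
                "settings.annual_discount_rate_outcomes",
            ),
            Bound("value", 0.0),
            Bound("value", 0.10),
        ),
        OneWayAnalysis(
            "outpatient_cost",
            ("unit_costs.cost_outpatient_nic", "unit_costs.cost_outpatient_ic"),
            Bound("multiplier", 0.5),
            Bound("multiplier", 1.5),
        ),
        OneWayAnalysis(
            "inpatient_cost",
            ("unit_costs.cost_inpatient_day",),
            Bound("multiplier", 0.5),
            Bound("multiplier", 1.5),
        ),
        OneWayAnalysis(
            "len_price",
            ("unit_costs.price_len_25mg",),
            Bound("multiplier", 0.6),
            Bound("multiplier", 1.4),
        ),
        OneWayAnalysis(
            "bort_price",
            ("unit_costs.price_bort_per_mg",),
            Bound("multiplier", 0.6),
            Bound("multiplier", 1.4),
        ),
        OneWayAnalysis(
            "preprog_utility",
            ("utilities.u_preprog_early", "utilities.u_preprog_late"),
            Bound("multiplier", 0.5),
            Bound("value", 1.0),
        ),
    ]
    for reg, sched in params.transition_schedules.items():
        tag = reg.replace("/", "_").lower()
        for k in range(1, len(sched.segments) + 1):
            for frm, to in (
                ("pre_progression", "progression"),
                ("pre_progression", "dead"),
                ("progression", "dead"),
            ):
                analyses.append(
                    OneWayAnalysis(
                        f"p_{tag}_seg{k}_{frm}_to_{to}",
                        (f"transitions.{reg}.{k}.{frm}.{to}",),
                        Bound("multiplier", 0.5),
                        Bound("multiplier", 1.5),
                    )
                )
    return analyses


@dataclass
class DSARow:
    analysis: OneWayAnalysis
    bound: str  # "low" | "high"
    table: CEATable


@dataclass
class DSAResult:
    rows: list[DSARow]
    base_table: CEATable


def run_one_way(params: ParameterSet, spec: list[OneWayAnalysis]) -> DSAResult:
    """Low and high full-CEA runs per analysis; the base parameter set is untouched."""
    base_table = compute_icers(evaluate_all(params))
    rows = []
    for analysis in spec:
        for bound_name in ("low", "high"):
            bound: Bound = getattr(analysis, bound_name)
            perturbed = bound.apply(params, analysis.targets)
            rows.append(
                DSARow(analysis, bound_name, compute_icers(evaluate_all(perturbed)))
            )
    return DSAResult(rows, base_table)


def dsa_frame(result: DSAResult) -> pd.DataFrame:
    """Long-format report: one row per analysis bound per strategy."""
    records = []
    for row in result.rows:
        for e in row.table.entries:
            records.append(
                {
                    "sensitivity": row.analysis.name,
                    "bound": row.bound,
                    "treatment": e.regimen,
                    "cost": e.total_cost,
                    "qalys": e.total_qalys,
                    "icer": e.icer,
                    "icer_label": e.icer_label,
                }
            )
    return pd.DataFrame.from_records(records)


def _strategy_icer(table: CEATable, regimen: str) -> float:
    """Frontier ICER used for tornado widths: dominated -> +inf, reference -> 0."""
    e = table.entry(regimen)
    if not e.on_frontier:
        return math.inf
    return 0.0 if e.icer is None else e.icer


def tornado_table(result: DSAResult, pivot: str) -> pd.DataFrame:
    """Rows sorted by descending |ICER(high) - ICER(low)| for strategy ``pivot``.

    An end at which the pivot strategy is dominated yields an infinite width
    and therefore sorts first; width ties keep a stable alphabetical order.
    """
    if not result.rows:
        return pd.DataFrame(
            columns=["parameter", "low_icer", "high_icer", "width", "base_icer"]
        )
    by_name: dict[str, dict[str, float]] = {}
    for row in result.rows:
        by_name.setdefault(row.analysis.name, {})[row.bound] = _strategy_icer(
            row.table, pivot
        )
    base = _strategy_icer(result.base_table, pivot)
    records = []
    for name in sorted(by_name):
        lo, hi = by_name[name].get("low"), by_name[name].get("high")
        width = abs(hi - lo)
        records.append(
            {
                "parameter": name,
                "low_icer": lo,
                "high_icer": hi,
                "width": width,
                "base_icer": base,
            }
        )
    records.sort(key=lambda r: -r["width"])
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of the price-threshold bisection for one regimen."""

    regimen: str
    cet: float
    achievable: bool
    multiplier: float | None
    reduction_pct: float | None
    icer_at_solution: float | None
    comparator: str | None
    iterations: int


def _frontier_icer_at(params: ParameterSet, regimen: str, price_path: str, m: float):
    perturbed = scale_parameter(params, price_path, m)
    table = compute_icers(evaluate_all(perturbed))
    e = table.entry(regimen)
    if not e.on_frontier:
        return math.inf, None
    return (0.0 if e.icer is None else e.icer), e.comparator


def threshold_price(
    params: ParameterSet,
    regimen: str,
    cet: float,
    rel_tol: float = 1e-4,
    max_iter: int = 60,
) -> ThresholdResult:
    """Find the drug-price reduction at which the regimen's frontier ICER equals ``cet``.

    Bisection on a multiplier in [0, 1] applied to the regimen's drug unit
    price; the full frontier is recomputed at every iterate. Returns a zero
    reduction when the regimen is already cost-effective, and flags the target
    as not achievable by price alone when the ICER exceeds ``cet`` even at a
    free drug.
    """
    if cet <= 0:
        raise ValueError("cet must be > 0")
    price_path = DRUG_PRICE_FIELD[regimen]
    icer_base, comp_base = _frontier_icer_at(params, regimen, price_path, 1.0)
    if icer_base <= cet:
        return ThresholdResult(regimen, cet, True, 1.0, 0.0, icer_base, comp_base, 0)
    icer_zero, _ = _frontier_icer_at(params, regimen, price_path, 0.0)
    if icer_zero > cet:
        return ThresholdResult(regimen, cet, False, None, None, None, None, 0)
    lo, hi = 0.0, 1.0  # ICER(lo) <= cet < ICER(hi); ICER monotone in price
    icer_mid, comp = icer_zero, None
    mid = lo
    for it in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        icer_mid, comp = _frontier_icer_at(params, regimen, price_path, mid)
        if math.isfinite(icer_mid) and abs(icer_mid - cet) / cet < rel_tol:
            break
        if icer_mid > cet:
            hi = mid
        else:
            lo = mid
    return ThresholdResult(
        regimen,
        cet,
        True,
        mid,
        (1.0 - mid) * 100.0,
        icer_mid if math.isfinite(icer_mid) else None,
        comp,
        it,
    )
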