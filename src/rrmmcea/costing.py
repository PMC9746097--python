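"""Per-cycle and cumulative treatment costs.

Three cost components accrue while patients occupy the cost-accruing states
(by default both alive states): drug acquisition (tiered dosing schedules at
unit prices), outpatient visits at the infusion or non-infusion chemotherapy
tariff, and inpatient days from adverse drug reactions. Totals are reported
both discounted and undiscounted, and the breakdown is exactly additive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import STATES, MarkovTrace, discount_factors
from .parameters import (
    DrugSchedule,
    EconomicSettings,
    ParameterSet,
    UnitCosts,
    UtilisationRates,
)

__all__ = [
    "RegimenCosting",
    "CostBreakdown",
    "costing_for",
    "drug_cost_per_cycle",
    "drug_cost_vector",
    "utilisation_cost_per_cycle",
    "discounted_costs",
    "one_year_costs",
    "cost_frame",
]


@dataclass(frozen=True)
class RegimenCosting:
    """Everything needed to cost one regimen against a cohort trace."""

    regimen: str
    drug_schedule: DrugSchedule
    utilisation: UtilisationRates
    unit_costs: UnitCosts
    accrual_states: tuple[str, ...] = ("pre_progression", "progression")


def costing_for(params: ParameterSet, regimen: str) -> RegimenCosting:
    if regimen not in params.drug_schedules:
        raise KeyError(f"unknown regimen {regimen!r}; have {list(params.drug_schedules)}")
    return RegimenCosting(
        regimen=regimen,
        drug_schedule=params.drug_schedules[regimen],
        utilisation=params.utilisation[regimen],
        unit_costs=params.unit_costs,
        accrual_states=params.cost_accrual_states,
    )


@dataclass(frozen=True)
class CostBreakdown:
    """Per-cycle cost components and their discounted/undiscounted totals.

    Arrays are indexed by cycle (cycle c at position c-1) and already weighted
    by cohort occupancy, so a sum over an array is a per-patient expectation.
    """

    pharmaceutical: np.ndarray
    outpatient: np.ndarray
    inpatient: np.ndarray
    discount: np.ndarray

    @property
    def total_per_cycle(self) -> np.ndarray:
        return self.pharmaceutical + self.outpatient + self.inpatient

    @property
    def pharmaceutical_total(self) -> float:
        return float(self.pharmaceutical @ self.discount)

    @property
    def outpatient_total(self) -> float:
        return float(self.outpatient @ self.discount)

    @property
    def inpatient_total(self) -> float:
        return float(self.inpatient @ self.discount)

    @property
    def non_pharmaceutical_total(self) -> float:
        return self.outpatient_total + self.inpatient_total

    @property
    def total(self) -> float:
        return self.pharmaceutical_total + self.outpatient_total + self.inpatient_total

    @property
    def undiscounted_total(self) -> float:
        return float(self.total_per_cycle.sum())


def drug_cost_per_cycle(costing: RegimenCosting, cycle: int) -> float:
    """Drug acquisition cost for one cycle: sum of units x unit price in the active tier."""
    tier = costing.drug_schedule.tier_at(cycle)
    return sum(
        comp.units_per_cycle * getattr(costing.unit_costs, comp.price_field)
        for comp in tier.components
    )


def drug_cost_vector(costing: RegimenCosting, n_cycles: int) -> np.ndarray:
    return np.array([drug_cost_per_cycle(costing, c) for c in range(1, n_cycles + 1)])


def utilisation_cost_per_cycle(costing: RegimenCosting) -> float:
    """Expected outpatient + inpatient cost per cycle (before occupancy weighting)."""
    out, inp = _utilisation_components(costing)
    return out + inp


def _utilisation_components(costing: RegimenCosting) -> tuple[float, float]:
    tariff = (
        costing.unit_costs.cost_outpatient_nic
        if costing.utilisation.outpatient_visit_type == "NIC"
        else costing.unit_costs.cost_outpatient_ic
    )
    outpatient = costing.utilisation.outpatient_visits_per_cycle * tariff
    inpatient = (
        costing.utilisation.inpatient_days_per_cycle
        * costing.unit_costs.cost_inpatient_day
    )
    return outpatient, inpatient


def _accrual_weights(
    trace: MarkovTrace, costing: RegimenCosting, settings: EconomicSettings, n: int
) -> np.ndarray:
    """Occupancy mass in the accrual states entering each of cycles 1..n."""
    idx = [STATES.index(s) for s in costing.accrual_states]
    occ = trace.occupancy
    rows = occ[:n, idx].sum(axis=1) if idx else np.zeros(n)
    if settings.half_cycle_correction:
        rows = 0.5 * (rows + occ[1 : n + 1, idx].sum(axis=1))
    return rows


def _breakdown(
    trace: MarkovTrace,
    costing: RegimenCosting,
    settings: EconomicSettings,
    n_cycles: int,
    discount: np.ndarray,
) -> CostBreakdown:
    alive = _accrual_weights(trace, costing, settings, n_cycles)
    drug = drug_cost_vector(costing, n_cycles)
    outpatient, inpatient = _utilisation_components(costing)
    return CostBreakdown(
        pharmaceutical=drug * alive,
        outpatient=np.full(n_cycles, outpatient) * alive,
        inpatient=np.full(n_cycles, inpatient) * alive,
        discount=discount,
    )


def discounted_costs(
    trace: MarkovTrace, costing: RegimenCosting, settings: EconomicSettings
) -> CostBreakdown:
    """Lifetime cost breakdown over the full horizon, discounted at the cost rate."""
    n = settings.n_cycles
    if trace.n_cycles != n:
        raise ValueError("trace and settings disagree on the number of cycles")
    discount = discount_factors(settings.annual_discount_rate_costs, settings)
    return _breakdown(trace, costing, settings, n, discount)


def one_year_costs(
    trace: MarkovTrace,
    costing: RegimenCosting,
    settings: EconomicSettings,
    horizon_cycles: int = 13,
    discount_within_year: bool = False,
) -> CostBreakdown:
    """Budget-impact horizon costs: truncated to ``horizon_cycles``, undiscounted by default.

    13 cycles of 28 days (364 days) is the closest whole-cycle approximation of
    one budget year.
    """
    if horizon_cycles < 0 or horizon_cycles > settings.n_cycles:
        raise ValueError("horizon_cycles must lie in [0, n_cycles]")
    if discount_within_year:
        discount = discount_factors(settings.annual_discount_rate_costs, settings)[
            :horizon_cycles
        ]
    else:
        discount = np.ones(horizon_cycles)
    return _breakdown(trace, costing, settings, horizon_cycles, discount)


def cost_frame(breakdown: CostBreakdown, regimen: str) -> pd.DataFrame:
    """Tidy per-cycle cost report: component, cycle, undiscounted, discounted."""
    n = len(breakdown.discount)
    frames = []
    for name, arr in (
        ("pharmaceutical", breakdown.pharmaceutical),
        ("outpatient", breakdown.outpatient),
        ("inpatient", breakdown.inpatient),
    ):
        frames.append(
            pd.DataFrame(
                {
                    "regimen": regimen,
                    "component": name,
                    "cycle": np.arange(1, n + 1),
                    "undiscounted": arr,
                    "discounted": arr * breakdown.discount,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
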