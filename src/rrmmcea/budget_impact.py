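"""One-year budget impact of each regimen for the national patient population.

The budget year is 13 cycles of 28 days. Per-patient first-year costs follow
the Markov trace (patients who die stop accruing) and are undiscounted within
the year by default, then scaled linearly by the target population, coverage
and per-regimen uptake fractions. Percentage increases are reported against
the standard-of-care (dexamethasone) scenario under identical settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .costing import costing_for, one_year_costs
from .markov import run_cohort_trace
from .parameters import ParameterSet, scale_parameter, set_parameter

__all__ = [
    "SOC_REGIMEN",
    "BIASettings",
    "BIAResult",
    "BIAScenario",
    "run_bia",
    "run_bia_mixed",
    "bia_sensitivity",
    "default_bia_grid",
    "bia_frame",
]

SOC_REGIMEN = "DEX"


@dataclass(frozen=True)
class BIASettings:
    """Population, horizon and adoption assumptions for the budget year."""

    population: float = 337
    horizon_cycles: int = 13
    uptake: dict[str, float] = field(default_factory=lambda: {SOC_REGIMEN: 1.0})
    coverage: float = 1.0
    discount_within_year: bool = False

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError("population must be >= 0")
        if not (0.0 <= self.coverage <= 1.0):
            raise ValueError("coverage must lie in [0, 1]")
        total = sum(self.uptake.values())
        if self.uptake and abs(total - 1.0) > 1e-9:
            raise ValueError(f"uptake fractions sum to {total!r}, not 1")
        if any(f < 0 for f in self.uptake.values()):
            raise ValueError("uptake fractions must be >= 0")


@dataclass(frozen=True)
class BIAResult:
    scenario: str
    pharmaceutical: float
    non_pharmaceutical: float
    pct_increase_vs_soc: float

    @property
    def total(self) -> float:
        return self.pharmaceutical + self.non_pharmaceutical


def _per_patient(params: ParameterSet, settings: BIASettings, regimen: str):
    """Per-patient first-year (pharmaceutical, non-pharmaceutical) costs."""
    trace = run_cohort_trace(params.transition_schedules[regimen], params.settings)
    breakdown = one_year_costs(
        trace,
        costing_for(params, regimen),
        params.settings,
        horizon_cycles=settings.horizon_cycles,
        discount_within_year=settings.discount_within_year,
    )
    return breakdown.pharmaceutical_total, breakdown.non_pharmaceutical_total


def _mixed_totals(params: ParameterSet, settings: BIASettings, uptake: dict[str, float]):
    n = settings.population * settings.coverage
    pharm = non_pharm = 0.0
    for regimen, fraction in uptake.items():
        if regimen not in params.transition_schedules:
            raise KeyError(f"unknown regimen {regimen!r}")
        p, np_ = _per_patient(params, settings, regimen)
        pharm += n * fraction * p
        non_pharm += n * fraction * np_
    return pharm, non_pharm


def _soc_total(params: ParameterSet, settings: BIASettings) -> float:
    p, np_ = _per_patient(params, settings, SOC_REGIMEN)
    return settings.population * settings.coverage * (p + np_)


def run_bia(params: ParameterSet, settings: BIASettings, regimen: str) -> BIAResult:
    """Budget impact of adopting one regimen for the whole covered population."""
    pharm, non_pharm = _mixed_totals(params, settings, {regimen: 1.0})
    soc = _soc_total(params, settings)
    pct = 0.0 if soc == 0 else ((pharm + non_pharm) / soc - 1.0) * 100.0
    return BIAResult(regimen, pharm, non_pharm, pct)


def run_bia_mixed(params: ParameterSet, settings: BIASettings) -> BIAResult:
    """Budget impact of a multi-regimen uptake mix (fractions must sum to 1)."""
    if not settings.uptake:
        raise ValueError("uptake mapping is empty")
    pharm, non_pharm = _mixed_totals(params, settings, settings.uptake)
    soc = _soc_total(params, settings)
    pct = 0.0 if soc == 0 else ((pharm + non_pharm) / soc - 1.0) * 100.0
    label = " + ".join(f"{reg} ({frac:.0%})" for reg, frac in settings.uptake.items())
    return BIAResult(label, pharm, non_pharm, pct)


@dataclass(frozen=True)
class BIAScenario:
    """One sensitivity scenario: parameter overrides plus adoption assumptions."""

    name: str
    set_values: dict[str, float] = field(default_factory=dict)
    scale_values: dict[str, float] = field(default_factory=dict)
    coverage: float | None = None
    uptake: dict[str, float] | None = None


def bia_sensitivity(
    params: ParameterSet, settings: BIASettings, grid: list[BIAScenario]
) -> list[tuple[BIAScenario, BIAResult, float]]:
    """One BIAResult per scenario, tagged with % change from the base-mix result.

    The change reference is the base-settings mix (its own-uptake run); the
    vs-standard-of-care percentage is carried inside each BIAResult as well, so
    both references are available.
    """
    base = run_bia_mixed(params, settings)
    out = []
    for scenario in grid:
        p = params
        for path, value in scenario.set_values.items():
            p = set_parameter(p, path, value)
        for path, mult in scenario.scale_values.items():
            p = scale_parameter(p, path, mult)
        s = replace(
            settings,
            coverage=scenario.coverage if scenario.coverage is not None else settings.coverage,
            uptake=dict(scenario.uptake) if scenario.uptake is not None else dict(settings.uptake),
        )
        result = run_bia_mixed(p, s)
        pct_vs_base = 0.0 if base.total == 0 else (result.total / base.total - 1.0) * 100.0
        out.append((scenario, result, pct_vs_base))
    return out


def default_bia_grid(regimen: str) -> list[BIAScenario]:
    """The published sensitivity grid for one adopted regimen.

    Unit-price bounds (lenalidomide R446.68-R2 233.38 per 25 mg, bortezomib
    R288.49-R2 442.45 per mg), population coverage 50-80%, and uptake mixes
    shared with the standard of care.
    """
    price_path = {
        "LEN/DEX": "unit_costs.price_len_25mg",
        "BORT": "unit_costs.price_bort_per_mg",
    }[regimen]
    price_bounds = {
        "LEN/DEX": (446.68, 2233.38),
        "BORT": (288.49, 2442.45),
    }[regimen]
    mixes = {
        "LEN/DEX": {"LEN/DEX": 0.5, SOC_REGIMEN: 0.5},
        "BORT": {"BORT": 0.8, SOC_REGIMEN: 0.2},
    }[regimen]
    lo, hi = price_bounds
    return [
        BIAScenario(f"{regimen} unit cost low", set_values={price_path: lo}, uptake={regimen: 1.0}),
        BIAScenario(f"{regimen} unit cost high", set_values={price_path: hi}, uptake={regimen: 1.0}),
        BIAScenario(f"{regimen} coverage 50%", coverage=0.5, uptake={regimen: 1.0}),
        BIAScenario(f"{regimen} coverage 80%", coverage=0.8, uptake={regimen: 1.0}),
        BIAScenario(f"{regimen} mixed uptake", uptake=mixes),
    ]


def bia_frame(results: list[tuple[BIAScenario, BIAResult, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scenario": scenario.name,
                "pharmaceutical": result.pharmaceutical,
                "non_pharmaceutical": result.non_pharmaceutical,
                "total": result.total,
                "pct_increase_vs_soc": result.pct_increase_vs_soc,
                "pct_change_vs_base": pct_vs_base,
            }
            for scenario, result, pct_vs_base in results
        ]
    )
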