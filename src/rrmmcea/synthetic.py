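"""Synthetic parameter sets and a patient-level microsimulation oracle.

The generator draws structurally valid parameter sets — row-stochastic
transition matrices with an absorbing death state and no recovery, utilities
ordered pre-progression >= progression >= 0, non-negative prices — by
perturbing a template (the bundled base case by default) with seeded
multiplier draws. Degenerate unit ranges reproduce the template exactly, so
the same machinery yields both fuzzing inputs and pinned fixtures.

The microsimulator replays the cohort model at the individual level with
per-cycle categorical draws, accruing QALYs and costs under exactly the same
start-of-cycle conventions as the cohort engine; at large n its occupancy
proportions and mean outcomes converge to the cohort trace, making it an
independent oracle for every pipeline stage.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .costing import costing_for, drug_cost_vector, utilisation_cost_per_cycle
from .markov import (
    DEAD,
    PRE_PROGRESSION,
    PROGRESSION,
    STATES,
    Segment,
    TransitionSchedule,
    UtilitySet,
    discount_factors,
)
from .parameters import ParameterSet, base_case

__all__ = ["SyntheticConfig", "MicrosimEstimate", "generate_parameter_set", "microsimulate"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Seeded perturbation ranges around a template parameter set.

    Each range is a (low, high) multiplier interval sampled uniformly; a
    degenerate (1, 1) range pins the corresponding quantities to the template.
    Probabilities are clamped so each row stays stochastic with death absorbing.
    """

    seed: int
    prob_multiplier_range: tuple[float, float] = (0.5, 1.5)
    utility_multiplier_range: tuple[float, float] = (0.7, 1.2)
    cost_multiplier_range: tuple[float, float] = (0.5, 2.0)
    units_multiplier_range: tuple[float, float] = (0.5, 2.0)
    randomize_boundaries: bool = False
    max_boundary_cycle: int = 60

    def __post_init__(self) -> None:
        for name in (
            "prob_multiplier_range",
            "utility_multiplier_range",
            "cost_multiplier_range",
            "units_multiplier_range",
        ):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name}: need 0 <= low <= high, got ({lo}, {hi})")


def _perturb_matrix(m: np.ndarray, rng: np.random.Generator, lo: float, hi: float) -> np.ndarray:
    """Scale each exit probability by an independent draw; stay absorbs the change."""
    out = m.copy()
    row_exits = {
        PRE_PROGRESSION: (PROGRESSION, DEAD),
        PROGRESSION: (DEAD,),
    }
    for row, exits in row_exits.items():
        total = 0.0
        for j in exits:
            p = min(1.0, m[row, j] * rng.uniform(lo, hi))
            p = min(p, 1.0 - total)
            out[row, j] = p
            total += p
        if np.array_equal(out[row], m[row]):
            continue  # degenerate (1, 1) range: keep the template row bit-exact
        out[row, row] = 1.0 - total
    out[DEAD] = (0.0, 0.0, 1.0)
    return out


def generate_parameter_set(
    config: SyntheticConfig, template: ParameterSet | None = None
) -> ParameterSet:
    """A random, fully valid parameter set; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    params = template if template is not None else base_case()
    out = copy.deepcopy(params)

    lo, hi = config.cost_multiplier_range
    uc = out.unit_costs
    uc = replace(
        uc,
        **{name: getattr(uc, name) * rng.uniform(lo, hi) for name in uc.__dataclass_fields__},
    )
    out = replace(out, unit_costs=uc)

    ulo, uhi = config.utility_multiplier_range
    u = out.utilities
    u_pre_early = min(1.0, u.u_preprog_early * rng.uniform(ulo, uhi))
    u_pre_late = min(u_pre_early, min(1.0, u.u_preprog_late * rng.uniform(ulo, uhi)))
    u_prog = min(u_pre_late, min(1.0, u.u_prog * rng.uniform(ulo, uhi)))
    out = replace(
        out,
        utilities=replace(
            u, u_preprog_early=u_pre_early, u_preprog_late=u_pre_late, u_prog=u_prog
        ),
    )

    nlo, nhi = config.units_multiplier_range
    for reg, sched in out.utilisation.items():
        out.utilisation[reg] = replace(
            sched,
            inpatient_days_per_cycle=sched.inpatient_days_per_cycle * rng.uniform(nlo, nhi),
            outpatient_visits_per_cycle=sched.outpatient_visits_per_cycle
            * rng.uniform(nlo, nhi),
        )

    plo, phi = config.prob_multiplier_range
    for reg, sched in out.transition_schedules.items():
        n_seg = len(sched.segments)
        if config.randomize_boundaries and n_seg > 1:
            bounds = np.sort(
                rng.choice(
                    np.arange(1, config.max_boundary_cycle), size=n_seg - 1, replace=False
                )
            )
            firsts = [1] + [int(b) + 1 for b in bounds]
            lasts = [int(b) for b in bounds] + [None]
        else:
            firsts = [s.first_cycle for s in sched.segments]
            lasts = [s.last_cycle for s in sched.segments]
        segments = tuple(
            Segment(f, l, _perturb_matrix(s.matrix, rng, plo, phi))
            for f, l, s in zip(firsts, lasts, sched.segments)
        )
        out.transition_schedules[reg] = TransitionSchedule(reg, segments)
    return out.check()


@dataclass(frozen=True)
class MicrosimEstimate:
    """Monte-Carlo state occupancy and outcome estimates from n individuals."""

    n_individuals: int
    occupancy: np.ndarray  # (n_cycles + 1, 3) proportions
    occupancy_se: np.ndarray  # binomial standard errors, same shape
    mean_qalys: float
    se_qalys: float
    mean_cost: float
    se_cost: float

    def frame(self) -> pd.DataFrame:
        n_rows = self.occupancy.shape[0]
        records = []
        for c in range(n_rows):
            for s, state in enumerate(STATES):
                records.append(
                    {
                        "cycle": c,
                        "state": state,
                        "proportion": self.occupancy[c, s],
                        "se": self.occupancy_se[c, s],
                    }
                )
        return pd.DataFrame.from_records(records)


def microsimulate(
    schedule: TransitionSchedule,
    params: ParameterSet,
    n: int,
    seed: int,
) -> MicrosimEstimate:
    """Simulate ``n`` independent patients through one regimen's schedule.

    Each patient starts pre-progression and transitions by categorical draws
    from the matrix active at each cycle. QALYs and costs accrue at the start
    of each cycle on the entering state — the cohort engine's convention — so
    any systematic disagreement with the cohort results isolates an engine bug
    rather than convention drift.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    settings = params.settings
    n_cycles = settings.n_cycles
    rng = np.random.default_rng(seed)

    utilities = params.utilities
    costing = costing_for(params, schedule.regimen)
    drug = drug_cost_vector(costing, n_cycles)
    util_cost = utilisation_cost_per_cycle(costing)
    accrual = np.zeros(3)
    for s in costing.accrual_states:
        accrual[STATES.index(s)] = 1.0
    cycle_years = settings.cycle_length_days / settings.days_per_year
    df_out = discount_factors(settings.annual_discount_rate_outcomes, settings)
    df_cost = discount_factors(settings.annual_discount_rate_costs, settings)

    states = np.zeros(n, dtype=np.int8)
    counts = np.zeros((n_cycles + 1, 3))
    counts[0, PRE_PROGRESSION] = n
    qalys = np.zeros(n)
    costs = np.zeros(n)

    for c in range(1, n_cycles + 1):
        w = utilities.weights(c)
        qalys += w[states] * cycle_years * df_out[c - 1]
        costs += accrual[states] * (drug[c - 1] + util_cost) * df_cost[c - 1]
        matrix = schedule.matrix_at(c)
        cum = matrix.cumsum(axis=1)
        draws = rng.random(n)
        states = (draws[:, None] > cum[states]).sum(axis=1).astype(np.int8)
        counts[c] = np.bincount(states, minlength=3)

    props = counts / n
    se = np.sqrt(props * (1.0 - props) / n)
    return MicrosimEstimate(
        n_individuals=n,
        occupancy=props,
        occupancy_se=se,
        mean_qalys=float(qalys.mean()),
        se_qalys=float(qalys.std(ddof=1) / np.sqrt(n)),
        mean_cost=float(costs.mean()),
        se_cost=float(costs.std(ddof=1) / np.sqrt(n)),
    )
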