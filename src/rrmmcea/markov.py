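"""Three-state Markov cohort engine.

The disease model has three health states — pre-progression (stable disease on
second-line treatment), progression, and dead — traversed by a closed cohort in
discrete cycles. Transition probabilities are time-inhomogeneous: a schedule of
row-stochastic 3x3 matrices, each valid over a contiguous range of cycles,
drives the cohort recursion ``occ[c] = occ[c-1] @ P(c)``. Death is absorbing
and there is no recovery from progression to pre-progression.

Quality-adjusted life years accrue at the start of each cycle on the entering
occupancy, weighted by state utilities (the pre-progression utility drops after
two years on treatment) and discounted at an annual rate compounded over the
cycle fraction of a year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import EconomicSettings

__all__ = [
    "STATES",
    "PRE_PROGRESSION",
    "PROGRESSION",
    "DEAD",
    "Segment",
    "TransitionSchedule",
    "UtilitySet",
    "MarkovTrace",
    "normalize_matrix",
    "validate_matrix",
    "derive_schedule_from_hazard_ratios",
    "run_cohort_trace",
    "discount_factor",
    "discount_factors",
    "discounted_qalys",
    "trace_frame",
]

STATES = ("pre_progression", "progression", "dead")
PRE_PROGRESSION, PROGRESSION, DEAD = 0, 1, 2

#: structural zeros of the model: no recovery, death absorbing
_STRUCTURAL_ZERO = ((1, 0), (2, 0), (2, 1))

ROW_SUM_TOL = 1e-9


def validate_matrix(matrix: np.ndarray, *, context: str = "matrix") -> list[str]:
    """Return a list of invariant violations for a transition matrix (empty if valid)."""
    errors: list[str] = []
    m = np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        return [f"{context}: expected shape (3, 3), got {m.shape}"]
    if np.any(m < -ROW_SUM_TOL) or np.any(m > 1 + ROW_SUM_TOL):
        errors.append(f"{context}: entries must lie in [0, 1]")
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if abs(s - 1.0) > 1e-9:
            errors.append(f"{context}: row {STATES[i]} sums to {s!r}, not 1")
    for i, j in _STRUCTURAL_ZERO:
        if m[i, j] != 0.0:
            errors.append(f"{context}: {STATES[i]}->{STATES[j]} must be 0")
    if not np.allclose(m[DEAD], [0.0, 0.0, 1.0]):
        errors.append(f"{context}: dead row must be (0, 0, 1)")
    return errors


def normalize_matrix(raw: Sequence[Sequence[float]] | np.ndarray) -> np.ndarray:
    """Renormalize a near-stochastic 3x3 matrix so each row sums to exactly 1.

    Published transition tables are rounded to two decimals, so row sums drift
    to 0.99 or 1.01; dividing each row by its sum restores a valid stochastic
    matrix while preserving structural zeros. Row sums outside [0.9, 1.1] are
    treated as data errors rather than rounding drift.
    """
    m = np.array(raw, dtype=float)
    if m.shape != (3, 3):
        raise ValueError(f"expected a 3x3 matrix, got shape {m.shape}")
    if np.any(m < 0):
        raise ValueError("transition probabilities must be non-negative")
    sums = m.sum(axis=1)
    for i, s in enumerate(sums):
        if not (0.9 <= s <= 1.1):
            raise ValueError(
                f"row {STATES[i]} sums to {s:g}, outside the rounding-drift band [0.9, 1.1]"
            )
    out = m / sums[:, None]
    errors = validate_matrix(out)
    if errors:
        raise ValueError("; ".join(errors))
    return out


@dataclass(frozen=True, eq=False)
class Segment:
    """A contiguous cycle range over which one transition matrix applies.

    ``last_cycle is None`` marks the open-ended final segment.
    """

    first_cycle: int
    last_cycle: int | None
    matrix: np.ndarray

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Segment):
            return NotImplemented
        return (
            self.first_cycle == other.first_cycle
            and self.last_cycle == other.last_cycle
            and np.array_equal(self.matrix, other.matrix)
        )

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        if self.first_cycle < 1:
            raise ValueError("first_cycle must be >= 1")
        if self.last_cycle is not None and self.last_cycle < self.first_cycle:
            raise ValueError("last_cycle must be >= first_cycle")

    def covers(self, cycle: int) -> bool:
        return cycle >= self.first_cycle and (
            self.last_cycle is None or cycle <= self.last_cycle
        )


@dataclass(frozen=True)
class TransitionSchedule:
    """Ordered, contiguous segments of transition matrices for one regimen."""

    regimen: str
    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        errors = self.validate()
        if errors:
            raise ValueError("; ".join(errors))

    def validate(self) -> list[str]:
        errors: list[str] = []
        segs = self.segments
        if not segs:
            return [f"{self.regimen}: schedule has no segments"]
        if segs[0].first_cycle != 1:
            errors.append(f"{self.regimen}: first segment must start at cycle 1")
        for a, b in zip(segs, segs[1:]):
            if a.last_cycle is None:
                errors.append(f"{self.regimen}: only the final segment may be open-ended")
            elif b.first_cycle != a.last_cycle + 1:
                errors.append(
                    f"{self.regimen}: segment starting at cycle {b.first_cycle} is not "
                    f"contiguous with the one ending at cycle {a.last_cycle}"
                )
        if segs[-1].last_cycle is not None:
            errors.append(f"{self.regimen}: final segment must be open-ended")
        for k, seg in enumerate(segs):
            errors.extend(
                validate_matrix(seg.matrix, context=f"{self.regimen} segment {k + 1}")
            )
        return errors

    def matrix_at(self, cycle: int) -> np.ndarray:
        if cycle < 1:
            raise ValueError("cycles are numbered from 1")
        for seg in self.segments:
            if seg.covers(cycle):
                return seg.matrix
        raise ValueError(f"{self.regimen}: no segment covers cycle {cycle}")


def derive_schedule_from_hazard_ratios(
    reference: TransitionSchedule,
    hr_progression: float,
    hr_death: float,
    *,
    regimen: str | None = None,
) -> TransitionSchedule:
    """Derive a comparator schedule by scaling the reference exit probabilities.

    The pre-progression -> progression probability is multiplied by
    ``hr_progression``; both death exits by ``hr_death``. Stay probabilities are
    rebalanced so each row remains stochastic; segment boundaries are inherited
    from the reference. Scaled exit mass exceeding 1 in any row is an error.
    """
    if hr_progression <= 0 or hr_death <= 0:
        raise ValueError("hazard ratios must be positive")
    new_segments = []
    for k, seg in enumerate(reference.segments):
        m = seg.matrix.copy()
        m[PRE_PROGRESSION, PROGRESSION] *= hr_progression
        m[PRE_PROGRESSION, DEAD] *= hr_death
        m[PROGRESSION, DEAD] *= hr_death
        for row in (PRE_PROGRESSION, PROGRESSION):
            exit_mass = m[row].sum() - m[row, row]
            if exit_mass > 1 + ROW_SUM_TOL:
                raise ValueError(
                    f"segment {k + 1}, row {STATES[row]}: scaled exit mass "
                    f"{exit_mass:g} exceeds 1"
                )
            m[row, row] = max(0.0, 1.0 - exit_mass)
        new_segments.append(Segment(seg.first_cycle, seg.last_cycle, m))
    return TransitionSchedule(regimen or reference.regimen, tuple(new_segments))


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights on the 0 (dead) to 1 (perfect health) scale.

    The pre-progression weight switches from ``u_preprog_early`` to
    ``u_preprog_late`` at ``late_switch_cycle``, reflecting declining quality of
    life after roughly two years on treatment.
    """

    u_preprog_early: float = 0.81
    u_preprog_late: float = 0.77
    late_switch_cycle: int = 27
    u_prog: float = 0.64
    u_dead: float = 0.0

    def __post_init__(self) -> None:
        for name in ("u_preprog_early", "u_preprog_late", "u_prog", "u_dead"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        if self.u_dead != 0.0:
            raise ValueError("u_dead must be 0")
        if self.late_switch_cycle < 1:
            raise ValueError("late_switch_cycle must be >= 1")

    def weights(self, cycle: int) -> np.ndarray:
        u_pre = self.u_preprog_early if cycle < self.late_switch_cycle else self.u_preprog_late
        return np.array([u_pre, self.u_prog, self.u_dead])


@dataclass(frozen=True)
class MarkovTrace:
    """Per-cycle state occupancy of a closed cohort; row 0 is the initial state."""

    occupancy: np.ndarray

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        if occ.ndim != 2 or occ.shape[1] != 3:
            raise ValueError("occupancy must be an (n_cycles + 1) x 3 array")
        if np.any(occ < -ROW_SUM_TOL) or np.any(occ > 1 + ROW_SUM_TOL):
            raise ValueError("occupancy entries must lie in [0, 1]")
        if np.any(np.abs(occ.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("each occupancy row must sum to 1 (cohort conservation)")
        if np.any(np.diff(occ[:, DEAD]) < -ROW_SUM_TOL):
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


def run_cohort_trace(
    schedule: TransitionSchedule, settings: "EconomicSettings"
) -> MarkovTrace:
    """Run the cohort recursion for ``settings.n_cycles`` cycles from 100% pre-progression."""
    n = settings.n_cycles
    occ = np.zeros((n + 1, 3))
    occ[0] = (1.0, 0.0, 0.0)
    for c in range(1, n + 1):
        occ[c] = occ[c - 1] @ schedule.matrix_at(c)
    return MarkovTrace(occ)


def discount_factor(cycle: int, annual_rate: float, settings: "EconomicSettings") -> float:
    """Discount factor for cycle ``cycle``: (1 + r)^-(cycle * cycle_days / days_per_year)."""
    if cycle < 1:
        raise ValueError("cycles are numbered from 1")
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    years = cycle * settings.cycle_length_days / settings.days_per_year
    return float((1.0 + annual_rate) ** (-years))


def discount_factors(annual_rate: float, settings: "EconomicSettings") -> np.ndarray:
    """Vector of per-cycle discount factors for cycles 1..n_cycles."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    cycles = np.arange(1, settings.n_cycles + 1)
    years = cycles * settings.cycle_length_days / settings.days_per_year
    return (1.0 + annual_rate) ** (-years)


def _reward_occupancy(trace: MarkovTrace, half_cycle: bool) -> np.ndarray:
    """Occupancy on which cycle rewards accrue: entering rows, or the mid-cycle mean."""
    occ = trace.occupancy
    if half_cycle:
        return 0.5 * (occ[:-1] + occ[1:])
    return occ[:-1]


def discounted_qalys(
    trace: MarkovTrace, utilities: UtilitySet, settings: "EconomicSettings"
) -> float:
    """Total discounted QALYs (in years) accumulated over the trace."""
    n = trace.n_cycles
    if n != settings.n_cycles:
        raise ValueError("trace and settings disagree on the number of cycles")
    cycle_years = settings.cycle_length_days / settings.days_per_year
    rows = _reward_occupancy(trace, settings.half_cycle_correction)
    weights = np.stack([utilities.weights(c) for c in range(1, n + 1)])
    df = discount_factors(settings.annual_discount_rate_outcomes, settings)
    return float(np.sum((rows * weights).sum(axis=1) * cycle_years * df))


def trace_frame(trace: MarkovTrace, settings: "EconomicSettings") -> pd.DataFrame:
    """Tidy per-cycle trace export with both discount-factor columns."""
    n = trace.n_cycles
    df_costs = discount_factors(settings.annual_discount_rate_costs, settings)
    df_out = discount_factors(settings.annual_discount_rate_outcomes, settings)
    records = []
    for c in range(n + 1):
        for s, state in enumerate(STATES):
            records.append(
                {
                    "cycle": c,
                    "state": state,
                    "occupancy": trace.occupancy[c, s],
                    "discount_factor_costs": 1.0 if c == 0 else df_costs[c - 1],
                    "discount_factor_outcomes": 1.0 if c == 0 else df_out[c - 1],
                }
            )
    return pd.DataFrame.from_records(records)
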