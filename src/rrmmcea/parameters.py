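"""Model inputs: economic settings, prices, utilisation, dosing, thresholds.

Everything the decision model consumes is bundled into a :class:`ParameterSet`
that can be validated, serialized to a versioned YAML schema, and perturbed
for sensitivity analysis through dotted parameter paths. The South African
second-line myeloma base case (2021 ZAR) ships both as an in-code constant
(:func:`base_case`) and as a bundled YAML file.
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .markov import (
    DEAD,
    PRE_PROGRESSION,
    PROGRESSION,
    STATES,
    Segment,
    TransitionSchedule,
    UtilitySet,
    normalize_matrix,
    validate_matrix,
)

__all__ = [
    "SCHEMA_VERSION",
    "REGIMENS",
    "EconomicSettings",
    "UnitCosts",
    "UtilisationRates",
    "DrugComponent",
    "DrugTier",
    "DrugSchedule",
    "CETRange",
    "ParameterSet",
    "ValidationError",
    "base_case",
    "load_parameters",
    "save_parameters",
    "parameters_from_dict",
    "parameters_to_dict",
    "adjust_private_price",
    "scale_parameter",
    "set_parameter",
    "valid_parameter_paths",
]

SCHEMA_VERSION = 1

#: the three second-line strategies compared throughout
REGIMENS = ("DEX", "BORT", "LEN/DEX")

ALIVE_STATES = ("pre_progression", "progression")


class ValidationError(ValueError):
    """Raised when a parameter set violates its invariants.

    ``errors`` enumerates every violation with a dotted field path.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class EconomicSettings:
    """Cycle structure, horizon and discounting conventions.

    28-day cycles run 195 times span just under 15 years, the assumed maximum
    survival of relapsed/refractory myeloma patients entering at median age 63.
    Costs and outcomes are both discounted at 5% per annum. The inflation rate
    and USD/ZAR exchange rate are retained as currency metadata only.
    """

    cycle_length_days: int = 28
    n_cycles: int = 195
    annual_discount_rate_costs: float = 0.05
    annual_discount_rate_outcomes: float = 0.05
    days_per_year: float = 365.25
    half_cycle_correction: bool = False
    currency_year: int = 2021
    inflation_rate: float = 0.051
    usd_zar_rate: float = 14.67

    def validate(self, prefix: str = "settings") -> list[str]:
        errors = []
        if self.cycle_length_days <= 0:
            errors.append(f"{prefix}.cycle_length_days: must be > 0")
        if self.n_cycles < 1:
            errors.append(f"{prefix}.n_cycles: must be >= 1")
        for name in ("annual_discount_rate_costs", "annual_discount_rate_outcomes"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                errors.append(f"{prefix}.{name}: {v!r} outside [0, 1]")
        if self.days_per_year <= 0:
            errors.append(f"{prefix}.days_per_year: must be > 0")
        return errors


@dataclass(frozen=True)
class UnitCosts:
    """Unit prices in 2021 ZAR (public-sector tender / UPFS tariffs)."""

    cost_inpatient_day: float = 4515.80
    cost_outpatient_nic: float = 800.00
    cost_outpatient_ic: float = 2837.00
    price_dex_40mg: float = 6.28
    price_len_25mg: float = 1340.03
    price_bort_per_mg: float = 865.47

    def validate(self, prefix: str = "unit_costs") -> list[str]:
        return [
            f"{prefix}.{name}: {getattr(self, name)!r} must be >= 0"
            for name in self.__dataclass_fields__
            if getattr(self, name) < 0
        ]


@dataclass(frozen=True)
class UtilisationRates:
    """Adverse-event-driven health-service use per 28-day cycle for one regimen."""

    inpatient_days_per_cycle: float
    outpatient_visits_per_cycle: float
    outpatient_visit_type: str  # "NIC" (non-infusion) or "IC" (infusion chemo)

    def validate(self, prefix: str) -> list[str]:
        errors = []
        if self.inpatient_days_per_cycle < 0:
            errors.append(f"{prefix}.inpatient_days_per_cycle: must be >= 0")
        if self.outpatient_visits_per_cycle < 0:
            errors.append(f"{prefix}.outpatient_visits_per_cycle: must be >= 0")
        if self.outpatient_visit_type not in ("NIC", "IC"):
            errors.append(
                f"{prefix}.outpatient_visit_type: {self.outpatient_visit_type!r} "
                "is not one of 'NIC', 'IC'"
            )
        return errors


@dataclass(frozen=True)
class DrugComponent:
    """One drug within a tier: units dispensed per cycle at a unit-price field."""

    drug: str
    units_per_cycle: float
    price_field: str

    def validate(self, prefix: str) -> list[str]:
        errors = []
        if self.units_per_cycle < 0:
            errors.append(f"{prefix}.units_per_cycle: must be >= 0")
        if self.price_field not in UnitCosts.__dataclass_fields__:
            errors.append(
                f"{prefix}.price_field: {self.price_field!r} is not a UnitCosts field"
            )
        return errors


@dataclass(frozen=True)
class DrugTier:
    first_cycle: int
    last_cycle: int | None
    components: tuple[DrugComponent, ...]

    def covers(self, cycle: int) -> bool:
        return cycle >= self.first_cycle and (
            self.last_cycle is None or cycle <= self.last_cycle
        )


@dataclass(frozen=True)
class DrugSchedule:
    """Dosing tiers for one regimen, e.g. a loading phase then maintenance."""

    tiers: tuple[DrugTier, ...]

    def validate(self, prefix: str) -> list[str]:
        errors = []
        tiers = self.tiers
        if not tiers:
            return [f"{prefix}: no tiers"]
        if tiers[0].first_cycle != 1:
            errors.append(f"{prefix}: first tier must start at cycle 1")
        for a, b in zip(tiers, tiers[1:]):
            if a.last_cycle is None:
                errors.append(f"{prefix}: only the final tier may be open-ended")
            elif b.first_cycle != a.last_cycle + 1:
                errors.append(
                    f"{prefix}: tier starting at cycle {b.first_cycle} not contiguous"
                )
        if tiers[-1].last_cycle is not None:
            errors.append(f"{prefix}: final tier must be open-ended")
        for i, tier in enumerate(tiers):
            for j, comp in enumerate(tier.components):
                errors.extend(comp.validate(f"{prefix}.tiers[{i}].components[{j}]"))
        return errors

    def tier_at(self, cycle: int) -> DrugTier:
        for tier in self.tiers:
            if tier.covers(cycle):
                return tier
        raise ValueError(f"no dosing tier covers cycle {cycle}")


@dataclass(frozen=True)
class CETRange:
    """Published South African cost-effectiveness thresholds (ZAR per QALY/DALY)."""

    primary_cet: float = 38_500.0
    low_cet: float = 32_659.0
    high_cet: float = 131_006.0

    def validate(self, prefix: str = "cets") -> list[str]:
        errors = []
        if min(self.primary_cet, self.low_cet, self.high_cet) <= 0:
            errors.append(f"{prefix}: thresholds must be > 0")
        if not (self.low_cet <= self.primary_cet <= self.high_cet):
            errors.append(f"{prefix}: expected low <= primary <= high")
        return errors


@dataclass(frozen=True)
class ParameterSet:
    """Complete model input bundle for one analysis run."""

    settings: EconomicSettings
    unit_costs: UnitCosts
    utilisation: dict[str, UtilisationRates]
    drug_schedules: dict[str, DrugSchedule]
    transition_schedules: dict[str, TransitionSchedule]
    utilities: UtilitySet
    cets: CETRange
    cost_accrual_states: tuple[str, ...] = ALIVE_STATES

    @property
    def regimens(self) -> tuple[str, ...]:
        return tuple(self.transition_schedules)

    def validate(self) -> list[str]:
        errors = list(self.settings.validate())
        errors += self.unit_costs.validate()
        errors += self.cets.validate()
        for reg in REGIMENS:
            for mapping, label in (
                (self.utilisation, "utilisation"),
                (self.drug_schedules, "drug_schedules"),
                (self.transition_schedules, "transition_schedules"),
            ):
                if reg not in mapping:
                    errors.append(f"{label}: missing regimen {reg!r}")
        for reg, rates in self.utilisation.items():
            errors += rates.validate(f"utilisation.{reg}")
        for reg, sched in self.drug_schedules.items():
            errors += sched.validate(f"drug_schedules.{reg}")
        for reg, tsched in self.transition_schedules.items():
            errors += [f"transition_schedules.{reg}: {e}" for e in tsched.validate()]
        for state in self.cost_accrual_states:
            if state not in ALIVE_STATES:
                errors.append(
                    f"cost_accrual_states: {state!r} is not an alive state "
                    f"{ALIVE_STATES}"
                )
        return errors

    def check(self) -> "ParameterSet":
        errors = self.validate()
        if errors:
            raise ValidationError(errors)
        return self


# --------------------------------------------------------------------------
# base case
# --------------------------------------------------------------------------

# Published monthly transition probabilities (one model cycle per month); rows
# carry +/-0.01 rounding drift and are renormalized on construction. Segment
# boundaries: months 0-6, 6-26, 26+.
_RAW_TRANSITIONS: dict[str, list[list[list[float]]]] = {
    "DEX": [
        [[0.80, 0.19, 0.02], [0.00, 0.88, 0.12], [0.0, 0.0, 1.0]],
        [[0.86, 0.14, 0.00], [0.00, 0.95, 0.05], [0.0, 0.0, 1.0]],
        [[0.92, 0.08, 0.00], [0.00, 0.94, 0.06], [0.0, 0.0, 1.0]],
    ],
    "BORT": [
        [[0.88, 0.10, 0.01], [0.00, 0.90, 0.10], [0.0, 0.0, 1.0]],
        [[0.92, 0.08, 0.00], [0.00, 0.96, 0.04], [0.0, 0.0, 1.0]],
        [[0.96, 0.04, 0.00], [0.00, 0.95, 0.05], [0.0, 0.0, 1.0]],
    ],
    "LEN/DEX": [
        [[0.92, 0.07, 0.01], [0.00, 0.92, 0.09], [0.0, 0.0, 1.0]],
        [[0.95, 0.05, 0.00], [0.00, 0.97, 0.03], [0.0, 0.0, 1.0]],
        [[0.97, 0.03, 0.00], [0.00, 0.96, 0.04], [0.0, 0.0, 1.0]],
    ],
}

_SEGMENT_BOUNDS = ((1, 6), (7, 26), (27, None))

# Oral dexamethasone tiering: 480 mg (12 x 40 mg) cycles 1-4, 160 mg thereafter.
# The LEN/DEX arm includes the same oral dexamethasone component alongside
# 21 x 25 mg lenalidomide per cycle.
_DEX_LOAD = DrugComponent("DEX", 12, "price_dex_40mg")
_DEX_MAINT = DrugComponent("DEX", 4, "price_dex_40mg")
_LEN = DrugComponent("LEN", 21, "price_len_25mg")


def _base_transition_schedule(regimen: str) -> TransitionSchedule:
    segments = tuple(
        Segment(first, last, normalize_matrix(raw))
        for (first, last), raw in zip(_SEGMENT_BOUNDS, _RAW_TRANSITIONS[regimen])
    )
    return TransitionSchedule(regimen, segments)


def base_case() -> ParameterSet:
    """The bundled base case: published prices, utilisation, dosing and matrices."""
    return ParameterSet(
        settings=EconomicSettings(),
        unit_costs=UnitCosts(),
        utilisation={
            "DEX": UtilisationRates(0.02, 0.3875, "NIC"),
            "BORT": UtilisationRates(0.0158, 0.5025, "IC"),
            "LEN/DEX": UtilisationRates(0.0125, 0.3325, "NIC"),
        },
        drug_schedules={
            "DEX": DrugSchedule(
                (
                    DrugTier(1, 4, (_DEX_LOAD,)),
                    DrugTier(5, None, (_DEX_MAINT,)),
                )
            ),
            "BORT": DrugSchedule(
                (
                    DrugTier(1, 8, (DrugComponent("BORT", 13.5, "price_bort_per_mg"),)),
                    DrugTier(9, None, (DrugComponent("BORT", 9.0, "price_bort_per_mg"),)),
                )
            ),
            "LEN/DEX": DrugSchedule(
                (
                    DrugTier(1, 4, (_LEN, _DEX_LOAD)),
                    DrugTier(5, None, (_LEN, _DEX_MAINT)),
                )
            ),
        },
        transition_schedules={reg: _base_transition_schedule(reg) for reg in REGIMENS},
        utilities=UtilitySet(),
        cets=CETRange(),
    ).check()


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def parameters_to_dict(params: ParameterSet) -> dict[str, Any]:
    def _tier(t: DrugTier) -> dict:
        return {
            "first_cycle": t.first_cycle,
            "last_cycle": t.last_cycle,
            "components": [
                {
                    "drug": c.drug,
                    "units_per_cycle": c.units_per_cycle,
                    "price_field": c.price_field,
                }
                for c in t.components
            ],
        }

    def _segment(s: Segment) -> dict:
        return {
            "first_cycle": s.first_cycle,
            "last_cycle": s.last_cycle,
            "matrix": [[float(x) for x in row] for row in s.matrix],
        }

    return {
        "schema_version": SCHEMA_VERSION,
        "settings": {k: getattr(params.settings, k) for k in EconomicSettings.__dataclass_fields__},
        "unit_costs": {k: getattr(params.unit_costs, k) for k in UnitCosts.__dataclass_fields__},
        "utilisation": {
            reg: {
                "inpatient_days_per_cycle": r.inpatient_days_per_cycle,
                "outpatient_visits_per_cycle": r.outpatient_visits_per_cycle,
                "outpatient_visit_type": r.outpatient_visit_type,
            }
            for reg, r in params.utilisation.items()
        },
        "drug_schedules": {
            reg: {"tiers": [_tier(t) for t in sched.tiers]}
            for reg, sched in params.drug_schedules.items()
        },
        "transition_schedules": {
            reg: {"segments": [_segment(s) for s in sched.segments]}
            for reg, sched in params.transition_schedules.items()
        },
        "utilities": {k: getattr(params.utilities, k) for k in UtilitySet.__dataclass_fields__},
        "cets": {k: getattr(params.cets, k) for k in CETRange.__dataclass_fields__},
        "cost_accrual_states": list(params.cost_accrual_states),
    }


def parameters_from_dict(data: Mapping[str, Any]) -> ParameterSet:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValidationError(
            [f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"]
        )
    errors: list[str] = []
    try:
        settings = EconomicSettings(**data["settings"])
    except (TypeError, ValueError, KeyError) as exc:
        raise ValidationError([f"settings: {exc}"]) from exc
    unit_costs = UnitCosts(**data.get("unit_costs", {}))
    utilisation = {
        reg: UtilisationRates(**r) for reg, r in data.get("utilisation", {}).items()
    }
    drug_schedules = {
        reg: DrugSchedule(
            tuple(
                DrugTier(
                    t["first_cycle"],
                    t["last_cycle"],
                    tuple(DrugComponent(**c) for c in t["components"]),
                )
                for t in sched["tiers"]
            )
        )
        for reg, sched in data.get("drug_schedules", {}).items()
    }
    transition_schedules = {}
    for reg, sched in data.get("transition_schedules", {}).items():
        try:
            transition_schedules[reg] = TransitionSchedule(
                reg,
                tuple(
                    Segment(
                        s["first_cycle"], s["last_cycle"], np.array(s["matrix"], float)
                    )
                    for s in sched["segments"]
                ),
            )
        except ValueError as exc:
            errors.append(f"transition_schedules.{reg}: {exc}")
    if errors:
        raise ValidationError(errors)
    params = ParameterSet(
        settings=settings,
        unit_costs=unit_costs,
        utilisation=utilisation,
        drug_schedules=drug_schedules,
        transition_schedules=transition_schedules,
        utilities=UtilitySet(**data.get("utilities", {})),
        cets=CETRange(**data.get("cets", {})),
        cost_accrual_states=tuple(data.get("cost_accrual_states", ALIVE_STATES)),
    )
    return params.check()


def load_parameters(path: str | Path) -> ParameterSet:
    """Load and fully validate a parameter file (versioned YAML schema)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise ValidationError([f"{path}: not a mapping"])
    return parameters_from_dict(data)


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(parameters_to_dict(params), fh, sort_keys=False)


def bundled_base_case_path() -> Path:
    """Path of the YAML copy of the base case shipped inside the package."""
    return Path(importlib.resources.files("rrmmcea") / "data" / "base_case.yaml")


# --------------------------------------------------------------------------
# price helpers and parameter paths
# --------------------------------------------------------------------------


def adjust_private_price(sep_price: float, reduction: float) -> float:
    """Convert a private-sector Single Exit Price to a public-sector estimate.

    The HTA methods guide convention applies a fractional ``reduction``
    (base case 0.40) to the SEP: ``sep_price * (1 - reduction)``.
    """
    if sep_price < 0:
        raise ValueError("sep_price must be >= 0")
    if not (0.0 <= reduction <= 1.0):
        raise ValueError("reduction must lie in [0, 1]")
    return sep_price * (1.0 - reduction)


def valid_parameter_paths(params: ParameterSet) -> list[str]:
    """All dotted paths accepted by :func:`scale_parameter` / :func:`set_parameter`."""
    paths = [f"unit_costs.{k}" for k in UnitCosts.__dataclass_fields__]
    paths += [
        "settings.annual_discount_rate_costs",
        "settings.annual_discount_rate_outcomes",
    ]
    paths += ["utilities.u_preprog_early", "utilities.u_preprog_late", "utilities.u_prog"]
    for reg in params.utilisation:
        paths += [
            f"utilisation.{reg}.inpatient_days_per_cycle",
            f"utilisation.{reg}.outpatient_visits_per_cycle",
        ]
    for reg, sched in params.transition_schedules.items():
        for k in range(1, len(sched.segments) + 1):
            for frm, to in (
                ("pre_progression", "progression"),
                ("pre_progression", "dead"),
                ("progression", "dead"),
            ):
                paths.append(f"transitions.{reg}.{k}.{frm}.{to}")
    return paths


def _unknown_path(params: ParameterSet, target: str) -> ValueError:
    return ValueError(
        f"unknown parameter path {target!r}; valid paths are: "
        + ", ".join(valid_parameter_paths(params))
    )


def _apply_to_path(params: ParameterSet, target: str, fn) -> ParameterSet:
    """Return a new ParameterSet with ``fn(old_value)`` written at ``target``."""
    parts = target.split(".")
    out = copy.deepcopy(params)
    if parts[0] == "unit_costs" and len(parts) == 2:
        if parts[1] not in UnitCosts.__dataclass_fields__:
            raise _unknown_path(params, target)
        new = replace(out.unit_costs, **{parts[1]: fn(getattr(out.unit_costs, parts[1]))})
        return replace(out, unit_costs=new)
    if parts[0] == "settings" and len(parts) == 2:
        if parts[1] not in (
            "annual_discount_rate_costs",
            "annual_discount_rate_outcomes",
        ):
            raise _unknown_path(params, target)
        new = replace(out.settings, **{parts[1]: fn(getattr(out.settings, parts[1]))})
        return replace(out, settings=new)
    if parts[0] == "utilities" and len(parts) == 2:
        if parts[1] not in ("u_preprog_early", "u_preprog_late", "u_prog"):
            raise _unknown_path(params, target)
        value = min(1.0, max(0.0, fn(getattr(out.utilities, parts[1]))))
        new = replace(out.utilities, **{parts[1]: value})
        return replace(out, utilities=new)
    if parts[0] == "utilisation" and len(parts) == 3:
        reg, field_name = parts[1], parts[2]
        if reg not in out.utilisation or field_name not in (
            "inpatient_days_per_cycle",
            "outpatient_visits_per_cycle",
        ):
            raise _unknown_path(params, target)
        rates = out.utilisation[reg]
        out.utilisation[reg] = replace(
            rates, **{field_name: fn(getattr(rates, field_name))}
        )
        return out
    if parts[0] == "transitions" and len(parts) == 5:
        reg, seg_no, frm, to = parts[1], parts[2], parts[3], parts[4]
        sched = out.transition_schedules.get(reg)
        if sched is None or not seg_no.isdigit():
            raise _unknown_path(params, target)
        k = int(seg_no) - 1
        if not (0 <= k < len(sched.segments)) or frm not in STATES or to not in STATES:
            raise _unknown_path(params, target)
        i, j = STATES.index(frm), STATES.index(to)
        if i == j or i == DEAD or (i, j) == (PROGRESSION, PRE_PROGRESSION):
            raise _unknown_path(params, target)
        seg = sched.segments[k]
        m = seg.matrix.copy()
        # Clamp the scaled probability to [0, 1] first, then to the mass left by
        # the other exit probabilities; the on-diagonal stay probability absorbs
        # the change so the row remains stochastic.
        new_p = min(1.0, max(0.0, fn(m[i, j])))
        other_exits = m[i].sum() - m[i, i] - m[i, j]
        new_p = min(new_p, 1.0 - other_exits)
        m[i, j] = new_p
        m[i, i] = 1.0 - other_exits - new_p
        segments = list(sched.segments)
        segments[k] = Segment(seg.first_cycle, seg.last_cycle, m)
        out.transition_schedules[reg] = TransitionSchedule(reg, tuple(segments))
        return out
    raise _unknown_path(params, target)


def scale_parameter(params: ParameterSet, target: str, multiplier: float) -> ParameterSet:
    """Return a copy of ``params`` with the value at ``target`` multiplied.

    Probabilities are clamped to [0, 1] (published convention: probabilities
    capped at 1 under +50% variation) with the stay probability rebalanced;
    utilities are clamped to [0, 1]. The input is never mutated.
    """
    return _apply_to_path(params, target, lambda v: v * multiplier).check()


def set_parameter(params: ParameterSet, target: str, value: float) -> ParameterSet:
    """Return a copy of ``params`` with the value at ``target`` replaced."""
    return _apply_to_path(params, target, lambda _v: value).check()
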