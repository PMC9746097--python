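"""Cohort engine: normalization, trace recursion, discounting, QALY accrual."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from rrmmcea import (
    Segment,
    TransitionSchedule,
    UtilitySet,
    derive_schedule_from_hazard_ratios,
    discount_factor,
    discounted_qalys,
    normalize_matrix,
    run_cohort_trace,
)
from rrmmcea.markov import DEAD, PRE_PROGRESSION, PROGRESSION, MarkovTrace, discount_factors
from rrmmcea.parameters import EconomicSettings


def homogeneous_schedule(matrix, regimen="X"):
    return TransitionSchedule(regimen, (Segment(1, None, np.asarray(matrix, float)),))


class TestNormalizeMatrix:
    def test_divides_rows_by_their_sums(self):
        raw = [[0.80, 0.19, 0.02], [0.0, 0.88, 0.12], [0.0, 0.0, 1.0]]
        out = normalize_matrix(raw)
        assert out[0] == pytest.approx(np.array([0.80, 0.19, 0.02]) / 1.01)
        assert out[0] == pytest.approx([0.7921, 0.1881, 0.0198], abs=5e-5)
        np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-12)

    def test_already_stochastic_row_unchanged(self):
        raw = [[0.92, 0.07, 0.01], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]]
        np.testing.assert_array_equal(normalize_matrix(raw), np.array(raw))

    def test_row_sum_outside_band_rejected(self):
        with pytest.raises(ValueError, match="pre_progression"):
            normalize_matrix([[0.5, 0.1, 0.1], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]])

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            normalize_matrix([[1.1, -0.05, 0.0], [0.0, 0.9, 0.1], [0.0, 0.0, 1.0]])

    @given(
        a=st.floats(0.0, 0.5), b=st.floats(0.0, 0.5), c=st.floats(0.0, 0.5),
        stay=st.floats(0.45, 1.0),
    )
    @hyp_settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_is_always_row_stochastic(self, a, b, c, stay):
        raw = np.array([[stay, a, b], [0.0, 1.0 - c, c], [0.0, 0.0, 1.0]])
        sums = raw.sum(axis=1)
        if np.all((sums >= 0.9) & (sums <= 1.1)):
            out = normalize_matrix(raw)
            np.testing.assert_allclose(out.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(out >= 0) and np.all(out <= 1)


class TestHazardRatioDerivation:
    def test_unit_ratios_reproduce_reference(self, base):
        ref = base.transition_schedules["LEN/DEX"]
        derived = derive_schedule_from_hazard_ratios(ref, 1.0, 1.0)
        for a, b in zip(ref.segments, derived.segments):
            np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-15)

    def test_progression_ratio_recovers_comparator_probability(self, base):
        # implied ratio between the published comparator and reference values
        ref = base.transition_schedules["LEN/DEX"]
        hr = 0.19 / 0.07
        derived = derive_schedule_from_hazard_ratios(ref, hr, 1.0)
        got = derived.segments[0].matrix[PRE_PROGRESSION, PROGRESSION]
        assert got == pytest.approx((0.07 / 1.0) * hr, rel=1e-12)

    def test_excess_exit_mass_rejected(self, base):
        ref = base.transition_schedules["LEN/DEX"]
        with pytest.raises(ValueError, match="exit mass"):
            derive_schedule_from_hazard_ratios(ref, 20.0, 1.0)

    def test_segment_boundaries_inherited(self, base):
        ref = base.transition_schedules["BORT"]
        derived = derive_schedule_from_hazard_ratios(ref, 1.2, 1.1)
        assert [(s.first_cycle, s.last_cycle) for s in derived.segments] == [
            (s.first_cycle, s.last_cycle) for s in ref.segments
        ]


class TestCohortTrace:
    def test_first_cycle_matches_matrix_row(self, base):
        trace = run_cohort_trace(
            base.transition_schedules["LEN/DEX"], base.settings
        )
        m = base.transition_schedules["LEN/DEX"].segments[0].matrix
        np.testing.assert_allclose(trace.occupancy[1], m[0], atol=1e-15)

    def test_second_cycle_preprogression_is_squared_stay(self, base):
        trace = run_cohort_trace(base.transition_schedules["LEN/DEX"], base.settings)
        stay = base.transition_schedules["LEN/DEX"].segments[0].matrix[0, 0]
        assert trace.occupancy[2, PRE_PROGRESSION] == pytest.approx(stay**2)
        # the published 0.92 row is already stochastic, so stay^2 = 0.8464
        assert trace.occupancy[2, PRE_PROGRESSION] == pytest.approx(0.8464, abs=1e-4)

    def test_instant_death_matrix_absorbs_cohort(self):
        kill = homogeneous_schedule([[0, 0, 1], [0, 0, 1], [0, 0, 1]])
        trace = run_cohort_trace(kill, EconomicSettings(n_cycles=10))
        np.testing.assert_array_equal(trace.occupancy[1:], np.tile([0, 0, 1.0], (10, 1)))

    @pytest.mark.parametrize("regimen", ["DEX", "BORT", "LEN/DEX"])
    def test_conservation_and_monotonicity(self, base, regimen):
        trace = run_cohort_trace(base.transition_schedules[regimen], base.settings)
        occ = trace.occupancy
        np.testing.assert_allclose(occ.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(occ[:, DEAD]) >= -1e-12)
        assert np.all(np.diff(occ[:, PRE_PROGRESSION]) <= 1e-12)

    def test_trace_invariants_enforced(self):
        bad = np.array([[1.0, 0.0, 0.0], [0.6, 0.3, 0.2]])
        with pytest.raises(ValueError, match="sum to 1"):
            MarkovTrace(bad)


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        s = EconomicSettings()
        assert discount_factor(50, 0.0, s) == 1.0

    def test_one_year_of_cycles_at_five_percent(self):
        # 13 cycles x 28 days = 364 days, just under one year
        s = EconomicSettings()
        assert discount_factor(13, 0.05, s) == pytest.approx(
            1.05 ** (-364 / 365.25)
        )
        assert round(discount_factor(13, 0.05, s), 4) == 0.9525

    def test_single_cycle_at_ten_percent(self):
        s = EconomicSettings()
        assert round(discount_factor(1, 0.10, s), 5) == 0.99272

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01, EconomicSettings())


class TestDiscountedQalys:
    def test_zero_utilities_annihilate(self, base):
        trace = run_cohort_trace(base.transition_schedules["DEX"], base.settings)
        zeros = UtilitySet(0.0, 0.0, 27, 0.0, 0.0)
        assert discounted_qalys(trace, zeros, base.settings) == 0.0

    def test_immortal_preprogression_cohort_closed_form(self):
        # perfect health, no discounting: total equals the full time horizon
        stay = homogeneous_schedule(np.eye(3))
        s = EconomicSettings(
            annual_discount_rate_costs=0.0, annual_discount_rate_outcomes=0.0
        )
        trace = run_cohort_trace(stay, s)
        q = discounted_qalys(trace, UtilitySet(1.0, 1.0, 27, 0.0, 0.0), s)
        assert q == pytest.approx(195 * 28 / 365.25)
        assert q == pytest.approx(14.95, abs=0.01)

    def test_discounting_reduces_qalys(self, base):
        trace = run_cohort_trace(base.transition_schedules["BORT"], base.settings)
        s0 = EconomicSettings(
            annual_discount_rate_costs=0.0, annual_discount_rate_outcomes=0.0
        )
        assert discounted_qalys(trace, base.utilities, base.settings) < discounted_qalys(
            trace, base.utilities, s0
        )

    def test_qalys_strictly_decrease_with_any_utility(self, base):
        trace = run_cohort_trace(base.transition_schedules["LEN/DEX"], base.settings)
        q = discounted_qalys(trace, base.utilities, base.settings)
        for lowered in (
            UtilitySet(0.80, 0.77, 27, 0.64),
            UtilitySet(0.81, 0.76, 27, 0.64),
            UtilitySet(0.81, 0.77, 27, 0.63),
        ):
            assert discounted_qalys(trace, lowered, base.settings) < q

    def test_geometric_series_closed_form_homogeneous(self):
        """Discounted occupancy totals match (I - dP)^-1 for a fixed matrix."""
        P = np.array([[0.9, 0.08, 0.02], [0.0, 0.93, 0.07], [0.0, 0.0, 1.0]])
        s = EconomicSettings(n_cycles=195)
        trace = run_cohort_trace(homogeneous_schedule(P), s)
        d = discount_factor(1, s.annual_discount_rate_outcomes, s)
        df = discount_factors(s.annual_discount_rate_outcomes, s)
        engine_totals = (trace.occupancy[:-1] * df[:, None]).sum(axis=0)
        n = s.n_cycles
        dP = d * P
        closed = (
            np.array([1.0, 0, 0])
            @ ((np.eye(3) - np.linalg.matrix_power(dP, n)) @ np.linalg.inv(np.eye(3) - dP))
            * d
        )
        np.testing.assert_allclose(engine_totals, closed, atol=1e-8)

    def test_half_cycle_correction_averages_boundary_rows(self, base):
        s_hc = EconomicSettings(half_cycle_correction=True)
        trace = run_cohort_trace(base.transition_schedules["DEX"], s_hc)
        q_start = discounted_qalys(trace, base.utilities, base.settings)
        q_half = discounted_qalys(trace, base.utilities, s_hc)
        # mid-cycle occupancy has strictly more dead mass than entering occupancy
        assert q_half < q_start
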