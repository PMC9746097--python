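"""Frontier assembly: ICERs, strict/extended dominance, verdicts, scenarios."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from rrmmcea import (
    CETRange,
    cet_verdict,
    compute_icers,
    evaluate_all,
    evaluate_strategy,
    pairwise_icer,
    scenario_without,
)
from rrmmcea.cea import StrategyResult


def s(regimen, cost, qalys):
    return StrategyResult(regimen, cost, qalys)


def frontier_oracle(results):
    """Independent frontier finder: a strategy survives iff no single strategy
    nor any convex mixture of two strategies weakly dominates it."""
    pts = {r.regimen: (r.total_cost, r.total_qalys) for r in results}
    survivors = set(pts)
    for name, (c, q) in pts.items():
        # strict dominance by a single alternative
        for other, (c2, q2) in pts.items():
            if other != name and c2 <= c and q2 >= q and (c2 < c or q2 > q):
                survivors.discard(name)
        # extended dominance by a mixture of two alternatives
        for (na, (ca, qa)), (nb, (cb, qb)) in itertools.combinations(pts.items(), 2):
            if name in (na, nb) or qa == qb:
                continue
            lam = (q - qb) / (qa - qb)
            if 0.0 <= lam <= 1.0:
                mix_cost = lam * ca + (1 - lam) * cb
                if mix_cost < c:
                    survivors.discard(name)
    return survivors


class TestEvaluateStrategy:
    def test_unknown_regimen_rejected(self, base):
        with pytest.raises(KeyError):
            evaluate_strategy(base, "THAL")

    def test_totals_are_positive_and_ordered(self, base_tables):
        results, _ = base_tables
        by_reg = {r.regimen: r for r in results}
        assert by_reg["DEX"].total_cost < by_reg["BORT"].total_cost
        assert by_reg["BORT"].total_cost < by_reg["LEN/DEX"].total_cost
        assert by_reg["DEX"].total_qalys < by_reg["BORT"].total_qalys
        assert by_reg["BORT"].total_qalys < by_reg["LEN/DEX"].total_qalys

    def test_zero_price_zero_utility_parameter_set(self, base):
        from dataclasses import replace
        from rrmmcea.parameters import UnitCosts
        from rrmmcea.markov import UtilitySet

        p = replace(
            base,
            unit_costs=UnitCosts(0, 0, 0, 0, 0, 0),
            utilities=UtilitySet(0.0, 0.0, 27, 0.0, 0.0),
        )
        r = evaluate_strategy(p, "BORT")
        assert (r.total_cost, r.total_qalys) == (0.0, 0.0)


class TestComputeIcers:
    def test_published_rounded_inputs(self):
        """Hand arithmetic on the published rounded cost/QALY table."""
        table = compute_icers(
            [s("DEX", 8_312, 1.14), s("BORT", 234_995, 1.49), s("LEN/DEX", 1_135_323, 2.22)]
        )
        assert table.entry("BORT").icer == pytest.approx(226_683 / 0.35, abs=1)
        assert table.entry("BORT").icer == pytest.approx(647_666, abs=1)
        assert table.entry("LEN/DEX").icer == pytest.approx(1_233_326, abs=1)
        assert [e.dominance for e in table.entries] == ["none"] * 3

    def test_equal_qalys_higher_cost_is_strictly_dominated(self):
        table = compute_icers([s("A", 100, 1.0), s("B", 200, 1.0)])
        assert table.entry("B").dominance == "strict"
        assert table.entry("B").icer is None

    def test_extended_dominance_detected_and_relabelled(self):
        # B's ICER vs A (1000) exceeds C's ICER vs B (500): B extended-dominated
        table = compute_icers([s("A", 0, 0.0), s("B", 1000, 1.0), s("C", 1500, 2.0)])
        assert table.entry("B").dominance == "extended"
        assert table.entry("C").comparator == "A"
        assert table.entry("C").icer == pytest.approx(750.0)
        assert table.entry("B").icer_label == "Dominated"

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            compute_icers([s("A", 1, 1), s("A", 2, 2)])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            compute_icers([s("A", 1, 1)])

    def test_equal_cost_tie_keeps_more_effective_first(self):
        table = compute_icers([s("A", 100, 1.0), s("B", 100, 2.0)])
        assert [e.regimen for e in table.entries] == ["B", "A"]
        assert table.entry("A").dominance == "strict"

    def test_exact_duplicates_flagged(self):
        table = compute_icers([s("A", 100, 1.0), s("B", 100, 1.0)])
        assert table.entry("B").duplicate_of == "A"

    def test_zero_incremental_cost_positive_qalys_is_free(self):
        # equal cost, more QALYs: the better strategy leads the frontier, the
        # other is dominated, and the head-to-head ratio is zero
        table = compute_icers([s("A", 100, 1.0), s("B", 100.0, 2.0), s("C", 300, 3.0)])
        assert table.entry("A").dominance == "strict"
        assert table.entries[0].regimen == "B"
        assert pairwise_icer(s("A", 100, 1.0), s("B", 100.0, 2.0)) == 0.0

    def test_frontier_icers_strictly_increase(self, base_tables):
        _, table = base_tables
        icers = [e.icer for e in table.frontier if e.icer is not None]
        assert icers == sorted(icers)
        assert all(a < b for a, b in zip(icers, icers[1:]))

    @given(
        data=st.lists(
            st.tuples(
                st.floats(0, 1e6, allow_nan=False), st.floats(0, 10, allow_nan=False)
            ),
            min_size=2,
            max_size=5,
        )
    )
    @hyp_settings(max_examples=100, deadline=None, derandomize=True)
    def test_frontier_matches_mixture_oracle(self, data):
        results = [s(f"S{i}", c, q) for i, (c, q) in enumerate(data)]
        if len({(c, q) for c, q in data}) != len(data):
            return  # exact duplicates resolved by id order; oracle is agnostic
        table = compute_icers(results)
        got = {e.regimen for e in table.frontier}
        assert got == frontier_oracle(results)

    def test_adding_dominated_strategy_leaves_icers_unchanged(self, base_tables):
        results, table = base_tables
        worst = StrategyResult("DUD", max(r.total_cost for r in results) + 1.0, 0.01)
        bigger = compute_icers(list(results) + [worst])
        assert bigger.entry("DUD").dominance == "strict"
        for reg in ("BORT", "LEN/DEX"):
            assert bigger.entry(reg).icer == pytest.approx(table.entry(reg).icer)


class TestVerdicts:
    def test_base_case_not_cost_effective_at_any_threshold(self, base, base_tables):
        _, table = base_tables
        verdicts = cet_verdict(table, base.cets)
        assert verdicts["DEX"]["primary_cet"]  # reference strategy
        for reg in ("BORT", "LEN/DEX"):
            assert not any(verdicts[reg].values())

    def test_boundary_icer_counts_as_cost_effective(self):
        table = compute_icers([s("A", 0, 0.0), s("B", 38_500, 1.0)])
        verdicts = cet_verdict(table, CETRange(38_500, 32_659, 131_006))
        assert verdicts["B"]["primary_cet"] is True
        assert verdicts["B"]["low_cet"] is False

    def test_verdicts_monotone_in_threshold(self, base_tables):
        _, table = base_tables
        cets = CETRange(38_500, 32_659, 131_006)
        verdicts = cet_verdict(table, cets)
        for reg, v in verdicts.items():
            # low <= primary <= high: cost-effectiveness can only switch on once
            flags = [v["low_cet"], v["primary_cet"], v["high_cet"]]
            assert flags == sorted(flags)


class TestScenario:
    def test_excluding_middle_strategy_changes_comparator(self, base, base_tables):
        results, table = base_tables
        reduced = scenario_without(base, "BORT")
        by_reg = {r.regimen: r for r in results}
        expected = pairwise_icer(by_reg["DEX"], by_reg["LEN/DEX"])
        assert reduced.entry("LEN/DEX").icer == pytest.approx(expected)
        assert reduced.entry("LEN/DEX").comparator == "DEX"
        # head-to-head against cheap SOC softens the ratio
        assert reduced.entry("LEN/DEX").icer < table.entry("LEN/DEX").icer

    def test_excluding_top_strategy_preserves_lower_frontier(self, base, base_tables):
        _, table = base_tables
        reduced = scenario_without(base, "LEN/DEX")
        assert reduced.entry("BORT").icer == pytest.approx(table.entry("BORT").icer)

    def test_unknown_exclusion_rejected(self, base):
        with pytest.raises(KeyError):
            scenario_without(base, "THAL")
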