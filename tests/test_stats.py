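"""Exact Fisher test against enumeration/scipy oracles; battery semantics."""

import math
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from mtoop import (AnalyzedSample, ContingencyTable, carrier_table,
                   fisher_exact_two_sided, lineage_frequency_tests,
                   run_category_comparisons)
from mtoop.annotate import AnnotatedVariant
from mtoop.errors import ValidationError


def enumeration_oracle(a, b, c, d):
    """Exact rational minlike p by enumerating all same-margin tables."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    probs = {}
    for x in range(max(0, k - r2), min(k, r1) + 1):
        probs[x] = Fraction(math.comb(r1, x) * math.comb(r2, k - x),
                            math.comb(n, k))
    observed = probs[a]
    return float(sum(p for p in probs.values() if p <= observed))


def oop_variant(oxphos=True, effect="synonymous", scores=None):
    return AnnotatedVariant("m.100A>G", 100, "substitution", "gene",
                            oxphos, effect, {}, scores or {}, None,
                            "out_of_place")


def sample(sid, cohort, variants=(), lineage="L0"):
    return AnalyzedSample(sid, cohort, list(variants), "L0a", 0.99, lineage)


class TestContingencyTable:
    def test_margins(self):
        t = ContingencyTable(2, 1, 1, 3)
        assert (t.n_cases, t.n_controls) == (3, 4)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 2, 3, 4)

    def test_odds_ratio_degenerate(self):
        assert math.isinf(ContingencyTable(2, 0, 1, 3).odds_ratio)
        assert math.isnan(ContingencyTable(0, 2, 0, 3).odds_ratio)
        assert ContingencyTable(0, 2, 1, 3).odds_ratio == 0.0


class TestFisherExact:
    def test_degenerate_single_table(self):
        assert fisher_exact_two_sided(ContingencyTable(2, 0, 2, 0)) == 1.0

    def test_closed_form_diagonal(self):
        # C(6,3) = 20 possible tables; the two extreme ones each have
        # probability 1/20, so the two-sided sum is 0.1
        p = fisher_exact_two_sided(ContingencyTable(3, 0, 0, 3))
        assert p == pytest.approx(0.1, rel=1e-12)

    def test_full_sweep_small_margins(self):
        for r1 in range(0, 9):
            for r2 in range(0, 9):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        t = ContingencyTable(a, r1 - a, c, r2 - c)
                        assert fisher_exact_two_sided(t) == pytest.approx(
                            enumeration_oracle(*t.cells()), rel=1e-9), t

    def test_matches_scipy_cross_check(self):
        from scipy.stats import fisher_exact as scipy_fisher
        for cells in [(8, 62, 3, 50), (42, 28, 12, 41), (1, 9, 5, 5),
                      (10, 0, 0, 10), (7, 21, 1, 38)]:
            a, b, c, d = cells
            ours = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
            theirs = scipy_fisher([[a, b], [c, d]])[1]
            assert ours == pytest.approx(theirs, rel=1e-8)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15),
           st.integers(0, 15), st.integers(0, 15))
    def test_transpose_and_swap_invariance(self, a, b, c, d):
        p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        assert 0.0 < p <= 1.0
        assert p == pytest.approx(fisher_exact_two_sided(
            ContingencyTable(a, c, b, d)), rel=1e-9)   # transpose
        assert p == pytest.approx(fisher_exact_two_sided(
            ContingencyTable(d, c, b, a)), rel=1e-9)   # row+column swap

    def test_one_sided_tail_monotonicity(self):
        # moving case carriers up at fixed margins shrinks the upper tail
        def upper_tail(a, b, c, d):
            r1, r2, k = a + b, c + d, a + c
            return sum(
                math.comb(r1, x) * math.comb(r2, k - x)
                for x in range(a, min(k, r1) + 1)
            ) / math.comb(r1 + r2, k)
        tails = [upper_tail(a, 10 - a, 10 - a, a) for a in range(5, 11)]
        assert all(t1 >= t2 for t1, t2 in zip(tails, tails[1:]))


class TestCarrierTable:
    def test_direct_count(self):
        cases = [sample("c1", "case", [oop_variant()]),
                 sample("c2", "case", [oop_variant()]),
                 sample("c3", "case")]
        controls = [sample("k1", "control", [oop_variant()]),
                    sample("k2", "control"), sample("k3", "control"),
                    sample("k4", "control")]
        t = carrier_table(cases, controls,
                          lambda v: v.placement == "out_of_place")
        assert t.cells() == (2, 1, 1, 3)

    def test_unsatisfied_predicate(self):
        cases = [sample("c1", "case", [oop_variant()])]
        controls = [sample("k1", "control")]
        t = carrier_table(cases, controls, lambda v: False)
        assert t.cells() == (0, 1, 0, 1)

    def test_multiple_qualifying_variants_count_once(self):
        one = [sample("c1", "case", [oop_variant()])]
        two = [sample("c1", "case", [oop_variant(), oop_variant()])]
        controls = [sample("k1", "control")]
        pred = lambda v: v.placement == "out_of_place"
        assert carrier_table(one, controls, pred).cells() == \
            carrier_table(two, controls, pred).cells()


class TestCategoryBattery:
    def test_bonferroni_alpha_is_0_0125(self):
        cases = [sample("c1", "case", [oop_variant()])]
        controls = [sample("k1", "control")]
        results = run_category_comparisons(cases, controls, 0.05)
        assert len(results) == 4
        assert all(r.alpha == pytest.approx(0.0125) for r in results)

    def test_exchangeable_groups_give_p_one(self):
        variants = [oop_variant(effect="non_synonymous",
                                scores={"APOGEE": 0.5})]
        cases = [sample(f"c{i}", "case", variants if i < 3 else [])
                 for i in range(6)]
        controls = [sample(f"k{i}", "control", variants if i < 3 else [])
                    for i in range(6)]
        for r in run_category_comparisons(cases, controls):
            assert r.p_value == 1.0 and not r.significant

    def test_categories_are_nested_filters(self):
        syn = oop_variant(effect="synonymous")
        non = oop_variant(effect="non_synonymous")
        scored = oop_variant(effect="non_synonymous", scores={"APOGEE": 0.9})
        non_ox = oop_variant(oxphos=False, effect="synonymous")
        cases = [sample("c1", "case", [syn]), sample("c2", "case", [non]),
                 sample("c3", "case", [scored]),
                 sample("c4", "case", [non_ox])]
        controls = [sample("k1", "control")]
        by_cat = {r.category: r.table.a
                  for r in run_category_comparisons(cases, controls)}
        assert by_cat == {"oxphos_any": 3, "oxphos_synonymous": 1,
                          "oxphos_non_synonymous": 2,
                          "oxphos_scored_non_synonymous": 1}


class TestLineageBattery:
    def test_identical_composition_gives_p_one(self):
        cases = [sample(f"c{i}", "case", lineage=l)
                 for i, l in enumerate(["L0", "L0", "L3"])]
        controls = [sample(f"k{i}", "control", lineage=l)
                    for i, l in enumerate(["L0", "L0", "L3"])]
        for r in lineage_frequency_tests(cases, controls):
            assert r.p_value == 1.0

    def test_constructed_l0_table_matches_oracle(self):
        cases = [sample(f"c{i}", "case", lineage="L0" if i < 32 else "L3")
                 for i in range(70)]
        controls = [sample(f"k{i}", "control",
                           lineage="L0" if i < 35 else "L3")
                    for i in range(53)]
        results = {r.category: r for r in
                   lineage_frequency_tests(cases, controls, alpha=0.0125)}
        r = results["lineage:L0"]
        assert r.table.cells() == (32, 38, 35, 18)
        assert r.p_value == pytest.approx(
            enumeration_oracle(32, 38, 35, 18), rel=1e-9)
        assert r.alpha == 0.0125

    def test_lineage_exclusive_to_one_group(self):
        cases = [sample(f"c{i}", "case", lineage="L1") for i in range(4)]
        controls = [sample(f"k{i}", "control", lineage="L2")
                    for i in range(4)]
        results = {r.category: r for r in
                   lineage_frequency_tests(cases, controls)}
        assert results["lineage:L1"].p_value == pytest.approx(
            enumeration_oracle(4, 0, 0, 4), rel=1e-9)
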