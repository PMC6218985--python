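"""Enrichment, promoter direction, pattern and consistency statistics."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdriver import (
    cross_cohort_consistency,
    fisher_combine,
    hypergeom_enrichment,
    identify_common_targets,
    pattern_tests,
    promoter_direction,
)
from methdriver.patterns import RegulatorLists, regulator_enrichment


def hypergeom_oracle(N, K, n, k):
    """Exact rational P(X >= k) by enumerating all C(N, n) draws."""
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        hits += sum(1 for x in draw if x < K) >= k
    return Fraction(hits, total)


class TestHypergeom:
    def test_printed_example(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_is_certain(self):
        assert hypergeom_enrichment(100, 10, 5, 0) == 1.0

    def test_degenerate_full_list(self):
        assert hypergeom_enrichment(8, 8, 3, 3) == pytest.approx(1.0, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 11, 4, 2)

    @pytest.mark.parametrize(
        "N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5), (9, 2, 7)]
    )
    def test_matches_exact_rational_enumeration(self, N, K, n):
        for k in range(0, min(K, n) + 1):
            expected = hypergeom_oracle(N, K, n, k)
            assert hypergeom_enrichment(N, K, n, k) == pytest.approx(
                float(expected), rel=1e-10
            )


class TestFisherCombine:
    def test_single_p_identity(self):
        assert fisher_combine([0.07]) == pytest.approx(0.07, rel=1e-9)

    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_known_chi_square_tail(self):
        # X^2 = -4 ln 0.05 = 11.983; df=4 survival = exp(-x/2)(1 + x/2)
        x2 = -4 * math.log(0.05)
        expected = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(0.01747, abs=1e-5)

    def test_zero_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            p = fisher_combine([0.0, 0.5])
        assert 0 <= p < 1e-100

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fisher_combine([])

    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=6), st.data())
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_monotone(self, ps, data):
        rnd = data.draw(st.randoms(use_true_random=False))
        shuffled = ps[:]
        rnd.shuffle(shuffled)
        assert fisher_combine(ps) == pytest.approx(fisher_combine(shuffled), rel=1e-12)
        i = data.draw(st.integers(0, len(ps) - 1))
        smaller = ps[:]
        smaller[i] = ps[i] / 2
        assert fisher_combine(smaller) <= fisher_combine(ps) + 1e-15


class TestPromoterDirection:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["hyper"] * 3 + ["hypo"], "hyper"),
            (["hyper", "hyper", "hypo", "hypo"], "none"),  # tie -> uncalled
            ([], "none"),
            (["none", "none"], "none"),
            (["hypo", "none", "hypo", "hyper"], "hypo"),
        ],
    )
    def test_majority_rule(self, calls, expected):
        assert promoter_direction(calls) == expected


class TestCommonTargets:
    def test_requires_significance_in_every_cohort(self):
        per_cohort = {
            "C1": {"g1": 0.04, "g2": 0.04, "g3": 0.2},
            "C2": {"g1": 0.03, "g2": 0.06, "g3": 0.01},
        }
        assert identify_common_targets(per_cohort, ["C1", "C2"]) == {"g1"}

    def test_vacuous_threshold_keeps_everything(self):
        per_cohort = {"C1": {"g1": 0.9, "g2": 0.5}}
        assert identify_common_targets(per_cohort, ["C1"], alpha=1.0) == {"g1", "g2"}

    def test_empty_cohort_set_rejected(self):
        with pytest.raises(ValueError):
            identify_common_targets({}, [])


class TestPatternTests:
    def test_all_none_gives_unit_pvalues(self):
        genes = [f"g{i}" for i in range(10)]
        dm = {"C1": {g: "none" for g in genes}}
        de = {"C1": {g: "none" for g in genes}}
        res = pattern_tests("drv", ["C1"], dm, de)
        assert res.p_dmde == 1.0
        assert all(p == 1.0 for p in res.pattern_p.values())
        assert all(c == [0] for c in res.pattern_counts.values())

    def test_single_cohort_matches_hypergeometric_example(self):
        # universe 10, 5 promoter-hyper genes, 4 down-regulated, all 4 in the
        # hyper set: P(X >= 4 | N=10, K=5, n=4) = 5/210
        genes = [f"g{i}" for i in range(10)]
        dm = {g: "none" for g in genes}
        de = {g: "none" for g in genes}
        for g in genes[:5]:
            dm[g] = "hyper"
        for g in genes[1:5]:
            de[g] = "down"
        res = pattern_tests("drv", ["C1"], {"C1": dm}, {"C1": de})
        assert res.pattern_p["+-"] == pytest.approx(5 / 210, rel=1e-9)
        assert res.pattern_counts["+-"] == [4]

    def test_pattern_counts_partition_the_overlap(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        dm = {g: rng.choice(["hyper", "hypo", "none"]) for g in genes}
        de = {g: rng.choice(["up", "down", "none"]) for g in genes}
        res = pattern_tests("drv", ["C1"], {"C1": dm}, {"C1": de})
        n_both = sum(
            1 for g in genes if dm[g] != "none" and de[g] != "none"
        )
        assert sum(c[0] for c in res.pattern_counts.values()) == n_both


class TestConsistency:
    def test_single_pair_median_is_that_pair(self):
        sets = {"C1": {"a", "b", "c"}, "C2": {"b", "c", "d"}}
        expected = hypergeom_enrichment(20, 3, 3, 2)
        assert cross_cohort_consistency(sets, 20) == pytest.approx(expected)

    def test_identical_large_sets_are_extremely_consistent(self):
        s = {f"g{i}" for i in range(10)}
        p = cross_cohort_consistency({"C1": s, "C2": s}, 100)
        # 1 / C(100, 10) ~ 5.8e-14
        assert p < 1e-10

    def test_disjoint_sets_uninformative(self):
        assert cross_cohort_consistency({"C1": {"a", "b"}, "C2": {"c", "d"}}, 100) == 1.0

    def test_single_cohort_yields_nan(self):
        assert math.isnan(cross_cohort_consistency({"C1": {"a"}}, 10))

    def test_median_over_three_pairs(self):
        sets = {"C1": {"a", "b"}, "C2": {"a", "b"}, "C3": {"c", "d"}}
        pairwise = [
            hypergeom_enrichment(10, 2, 2, 2),  # C1-C2
            hypergeom_enrichment(10, 2, 2, 0),  # C1-C3
            hypergeom_enrichment(10, 2, 2, 0),  # C2-C3
        ]
        assert cross_cohort_consistency(sets, 10) == pytest.approx(
            sorted(pairwise)[1]
        )


def test_regulator_lists_restricted_to_universe():
    lists = RegulatorLists(
        list_a=frozenset({"r1", "r2", "r3"}), list_b=frozenset({"r1"})
    )
    universe = {"r1", "r2", "t1", "t2", "t3"}
    restricted = lists.restrict(universe)
    assert restricted.list_a == {"r1", "r2"}
    k, p = regulator_enrichment({"r1", "t1"}, lists.list_a, universe)
    assert k == 1
    assert p == pytest.approx(float(hypergeom_oracle(5, 2, 2, 1)), rel=1e-9)
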