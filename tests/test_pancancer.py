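"""Pan-cancer resampling p-values, grouped BH and driver-call assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methdriver import (
    bh_adjust_grouped,
    call_drivers,
    eligible_cohorts,
    empirical_p_per_cancer,
    pan_cancer_p,
    pan_cancer_p_exact,
)
from methdriver.nullpool import CancerLevelCall
from methdriver.pancancer import DriverCall

from test_nullpool import bundle_with_counts, pool_of


def enumerate_sum_tail(values, m, observed):
    """P(sum of m i.i.d. pool draws >= observed) by full enumeration."""
    total = hits = 0
    for combo in itertools.product(values, repeat=m):
        total += 1
        hits += sum(combo) >= observed
    return hits / total


def bh_oracle(ps):
    """Step-up BH: p_adj(i) = min_{j>=i} p_(j) * n / j, capped at 1."""
    n = len(ps)
    order = sorted(range(n), key=lambda i: ps[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, ps[i] * n / rank)
        adj[i] = running
    return adj


class TestPanCancerExact:
    def test_two_draw_enumeration(self):
        # pool [1,2,3], m=2: only (3,3) of the 9 pairs sums to >= 6
        assert pan_cancer_p_exact(6, pool_of([1, 2, 3]), m=2) == pytest.approx(
            1 / 9, rel=1e-12
        )

    def test_minimal_observed_sum_is_certain(self):
        assert pan_cancer_p_exact(2, pool_of([1, 2, 3]), m=2) == 1.0
        assert pan_cancer_p_exact(0, pool_of([1, 2, 3]), m=3) == 1.0

    def test_single_draw_reduces_to_per_cancer_p(self):
        pool = pool_of([5, 10, 15, 10])
        for obs in (0, 5, 9, 10, 16):
            assert pan_cancer_p_exact(obs, pool, m=1) == pytest.approx(
                empirical_p_per_cancer(obs, pool), abs=1e-12
            )

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_full_enumeration_on_random_pools(self, m):
        rng = np.random.default_rng(42)
        for _ in range(10):
            values = list(rng.integers(0, 12, size=rng.integers(2, 6)))
            observed = int(rng.integers(0, sum(sorted(values)[-1:]) * m + 2))
            assert pan_cancer_p_exact(observed, pool_of(values), m) == pytest.approx(
                enumerate_sum_tail(values, m, observed), rel=1e-12
            )

    def test_oversized_support_refused(self):
        with pytest.raises(ValueError, match="Monte-Carlo"):
            pan_cancer_p_exact(10, pool_of([10**7]), m=5)


class TestPanCancerMonteCarlo:
    def test_within_three_sigma_of_enumeration(self):
        B = 100_000
        rng = np.random.default_rng(7)
        for trial in range(20):
            values = list(rng.integers(0, 15, size=int(rng.integers(3, 6))))
            m = int(rng.integers(1, 4))
            # target a non-degenerate tail probability
            sums = sorted(
                sum(c) for c in itertools.product(values, repeat=m)
            )
            observed = sums[len(sums) // 2]
            pool = pool_of(values)
            p_exact = pan_cancer_p_exact(observed, pool, m)
            p_mc = pan_cancer_p(observed, pool, m, B=B, seed=1000 + trial)
            tol = 3 * np.sqrt(p_exact * (1 - p_exact) / B)
            assert abs(p_mc - p_exact) <= max(tol, 1e-12)

    def test_seed_reproducibility(self):
        pool = pool_of([1, 5, 9, 2])
        a = pan_cancer_p(10, pool, m=2, B=5000, seed=3)
        b = pan_cancer_p(10, pool, m=2, B=5000, seed=3)
        assert a == b


class TestGroupedBH:
    def test_single_gene_group_unchanged(self):
        assert bh_adjust_grouped({"g": 0.03}, {"g": 1}) == {"g": 0.03}

    def test_uniform_ladder_collapses_to_max(self):
        ps = {f"g{i}": p for i, p in enumerate([0.01, 0.02, 0.03, 0.04])}
        adj = bh_adjust_grouped(ps, {g: 2 for g in ps})
        assert all(v == pytest.approx(0.04, rel=1e-12) for v in adj.values())

    def test_grouping_changes_the_outcome(self):
        # pooled BH over {0.025, 0.025, 0.05} would give 0.0375 to the first
        # two; stratified, the singleton keeps 0.025 and the pair (0.025,
        # 0.05) adjusts to (0.05, 0.05)
        ps = {"a": 0.025, "b": 0.025, "c": 0.05}
        adj = bh_adjust_grouped(ps, {"a": 1, "b": 2, "c": 2})
        assert adj["a"] == pytest.approx(0.025, rel=1e-12)
        assert adj["b"] == pytest.approx(0.05, rel=1e-12)
        assert adj["c"] == pytest.approx(0.05, rel=1e-12)

    @given(
        st.lists(st.floats(0, 1), min_size=1, max_size=12),
        st.data(),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_step_up_oracle(self, ps, data):
        groups = [data.draw(st.integers(1, 3)) for _ in ps]
        named_p = {f"g{i}": p for i, p in enumerate(ps)}
        named_g = {f"g{i}": g for i, g in enumerate(groups)}
        adj = bh_adjust_grouped(named_p, named_g)
        for stratum in set(groups):
            idx = [i for i, g in enumerate(groups) if g == stratum]
            oracle = bh_oracle([ps[i] for i in idx])
            for j, i in enumerate(idx):
                assert adj[f"g{i}"] == pytest.approx(oracle[j], rel=1e-9, abs=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust_grouped({"g": 1.5}, {"g": 1})


class TestDriverCalls:
    @staticmethod
    def _calls(gene, per_cohort):
        return [
            CancerLevelCall(gene, c, p, "none", np_, nm)
            for c, p, np_, nm in per_cohort
        ]

    def test_eligibility_threshold(self):
        cohorts = [
            bundle_with_counts([6], "C01", seed=0),
            bundle_with_counts([4], "C02", seed=1),
            bundle_with_counts([5], "C03", seed=2),
        ]
        assert eligible_cohorts(cohorts, "g0") == {"C01", "C03"}
        assert eligible_cohorts(cohorts, "g0", min_mutated=1) == {"C01", "C02", "C03"}
        assert eligible_cohorts(cohorts, "absent") == set()

    def test_discordant_directions_called_both(self):
        calls = self._calls("g", [("C1", 0.01, 10, 2), ("C2", 0.01, 2, 10)])
        (dc,) = call_drivers(
            calls, {"g": 0.001}, {"g": 0.04}, {"g": {"C1", "C2"}}, {"g": 24}
        )
        assert dc.is_driver and dc.direction == "both"
        assert dc.T_plus == {"C1"} and dc.T_minus == {"C2"}

    def test_driver_with_no_significant_cohort_has_no_direction(self):
        # significant pan-cancer evidence can coexist with empty T_i
        calls = self._calls("g", [("C1", 0.30, 10, 2), ("C2", 0.20, 2, 10)])
        (dc,) = call_drivers(
            calls, {"g": 0.001}, {"g": 0.04}, {"g": {"C1", "C2"}}, {"g": 24}
        )
        assert dc.is_driver and dc.direction == "none" and not dc.T_i

    def test_above_alpha_not_a_driver(self):
        calls = self._calls("g", [("C1", 0.01, 10, 2)])
        (dc,) = call_drivers(calls, {"g": 0.03}, {"g": 0.06}, {"g": {"C1"}}, {"g": 12})
        assert not dc.is_driver

    def test_missing_per_cohort_calls_rejected(self):
        with pytest.raises(ValueError, match="no per-cohort"):
            call_drivers([], {"g": 0.01}, {"g": 0.01}, {"g": {"C1"}}, {"g": 5})

    def test_invariants_enforced_by_construction(self):
        with pytest.raises(ValueError, match="subset"):
            DriverCall(
                gene="g", modality="methylation",
                A_i=frozenset({"C1"}), T_i=frozenset({"C1", "C2"}),
                T_plus=frozenset({"C1", "C2"}), T_minus=frozenset(),
                observed_sum=1, p_i=0.1, p_adj=0.1,
                direction="hyper", is_driver=False,
            )
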