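"""Positional rank-sum tests, the scan statistic, candidate-region
enumeration and Monte-Carlo SVR calling."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import diffscan as ds
from diffscan import PositionalPValues, ValidationError
from diffscan.scan import (
    NullCache,
    rank_sum_pvalue,
    simulate_windowed_null,
    _exact_two_sided_p,
)

from conftest import make_dataset


def brute_force_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(m+n, m) labelings."""
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    m = len(a)
    w_obs = ranks[:m].sum()
    mu = m * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestRankSumPValue:
    def test_fully_separated_samples_give_2_over_252(self):
        p = rank_sum_pvalue(np.arange(1.0, 6.0), np.arange(6.0, 11.0))
        assert p == pytest.approx(2 / 252, abs=1e-12)

    def test_identical_samples_give_one(self):
        a = np.array([0.2, 0.4, 0.9])
        assert rank_sum_pvalue(a, a.copy()) == 1.0

    @pytest.mark.parametrize("m,n,seed", [(4, 4, 0), (5, 3, 1), (6, 6, 2)])
    def test_matches_brute_force_enumeration(self, m, n, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(m), rng.random(n)
        assert rank_sum_pvalue(a, b) == pytest.approx(
            brute_force_ranksum_p(a, b), abs=1e-10
        )

    def test_vectorized_exact_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        for m, n in [(10, 10), (20, 20), (7, 13)]:
            a, b = rng.random(m), rng.random(n)
            ranks = stats.rankdata(np.concatenate([a, b]))
            w = np.array([ranks[:m].sum()])
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert _exact_two_sided_p(m, n, w)[0] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            rank_sum_pvalue(np.array([]), np.array([1.0]))


class TestPositionalPValues:
    def test_identical_conditions_give_all_ones(self, identical_dataset):
        pv = ds.positional_pvalues(identical_dataset)["tx1"]
        np.testing.assert_array_equal(pv.p, np.ones(120))

    def test_window_truncated_at_transcript_ends(self, rng):
        """Position 1 with radius 2 pools positions 1-3 only."""
        a = rng.random(6)
        b = rng.random(6)
        dataset = make_dataset([a], [b])
        pv = ds.positional_pvalues(dataset, radius=2)["tx1"]
        assert pv.p[0] == pytest.approx(rank_sum_pvalue(a[:3], b[:3]))
        assert pv.p[3] == pytest.approx(rank_sum_pvalue(a[1:6], b[1:6]))

    def test_sparse_positions_untestable(self):
        a = np.array([0.1, np.nan, np.nan, np.nan, np.nan, 0.5, 0.7, 0.2])
        b = np.full(8, 0.3)
        pv = ds.positional_pvalues(make_dataset([a], [b]), radius=1)["tx1"]
        # windows around the NaN run have < 3 non-missing values in A
        assert np.isnan(pv.p[1:5]).all()

    def test_requires_two_conditions(self, rng):
        dataset = ds.ReactivityDataset(
            [ds.ReactivityProfile("t", "A", "r1", rng.random(10))]
        )
        with pytest.raises(ValidationError):
            ds.positional_pvalues(dataset)


class TestScanStatistic:
    def test_all_ones_give_zero(self):
        assert ds.scan_statistic([1.0, 1.0, 1.0]) == 0.0

    def test_single_p(self):
        assert ds.scan_statistic([0.05]) == pytest.approx(2.9957, abs=1e-4)

    def test_two_equal_ps(self):
        assert ds.scan_statistic([0.01, 0.01]) == pytest.approx(6.5127, abs=1e-4)

    def test_rejects_empty_and_out_of_range(self):
        with pytest.raises(ValidationError):
            ds.scan_statistic([])
        with pytest.raises(ValidationError):
            ds.scan_statistic([0.0, 0.5])
        with pytest.raises(ValidationError):
            ds.scan_statistic([1.5])

    @given(st.lists(st.floats(1e-9, 1.0), min_size=1, max_size=20), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_copy_scaling(self, ps, seed):
        rng = np.random.default_rng(seed)
        q = ds.scan_statistic(ps)
        assert ds.scan_statistic(rng.permutation(ps)) == pytest.approx(q, rel=1e-12)
        m = rng.integers(1, 5)
        single = ps[0]
        assert ds.scan_statistic([single] * int(m)) == pytest.approx(
            math.sqrt(m) * -math.log(single), rel=1e-12
        )

    def test_strictly_decreasing_in_each_p(self):
        base = [0.3, 0.6, 0.9]
        q0 = ds.scan_statistic(base)
        for i in range(3):
            lowered = list(base)
            lowered[i] *= 0.5
            assert ds.scan_statistic(lowered) > q0


class TestEnumerateCandidateRegions:
    def test_counts_all_windows(self):
        pv = PositionalPValues("t", [0.5, 0.5, 0.5])
        regions = ds.enumerate_candidate_regions(pv, L_min=1, L_max=3)
        assert len(regions) == 6
        assert sorted((r.start, r.end) for r in regions) == [
            (1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (3, 3)
        ]

    def test_no_region_spans_missing_position(self):
        pv = PositionalPValues("t", [0.5, 0.5, np.nan, 0.5, 0.5])
        regions = ds.enumerate_candidate_regions(pv, L_min=1, L_max=5)
        assert all(not (r.start <= 3 <= r.end) for r in regions)
        assert len(regions) == 6  # 2x(two length-1) + 2x(one length-2)

    def test_lmax_clamped_to_length(self):
        pv = PositionalPValues("t", [0.5, 0.5])
        regions = ds.enumerate_candidate_regions(pv, L_min=1, L_max=100)
        assert max(r.length for r in regions) == 2

    def test_q_matches_scan_statistic(self, rng):
        p = rng.uniform(0.01, 1.0, 8)
        pv = PositionalPValues("t", p)
        for r in ds.enumerate_candidate_regions(pv, 1, 8):
            assert r.q == pytest.approx(
                ds.scan_statistic(p[r.start - 1 : r.end]), rel=1e-12
            )

    @pytest.mark.parametrize("seed", range(20))
    def test_argmax_matches_brute_force_double_loop(self, seed):
        """Enumerate+argmax equals an O(n^2) double-loop oracle, Q to 1e-12."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 31))
        p = rng.uniform(1e-6, 1.0, n)
        pv = PositionalPValues("t", p)
        regions = ds.enumerate_candidate_regions(pv, 1, n)
        best = max(regions, key=lambda r: r.q)
        # oracle: all (start, end) pairs
        best_oracle, q_oracle = None, -np.inf
        for s in range(n):
            for e in range(s, n):
                q = -np.log(p[s : e + 1]).sum() / math.sqrt(e - s + 1)
                if q > q_oracle:
                    q_oracle, best_oracle = q, (s + 1, e + 1)
        assert (best.start, best.end) == best_oracle
        assert best.q == pytest.approx(q_oracle, abs=1e-12)


class TestNullDistributions:
    def test_uniform_null_deterministic_under_seed(self):
        n1 = ds.simulate_null_distribution(50, B=200, seed=42)
        n2 = ds.simulate_null_distribution(50, B=200, seed=42)
        np.testing.assert_array_equal(n1.samples, n2.samples)

    def test_single_position_null_matches_closed_form(self):
        """n=1, L=1: T_b = -log U_b, so P(T > -log 0.05) = 0.05."""
        B = 4000
        null = ds.simulate_null_distribution(1, L_min=1, L_max=1, B=B, seed=9)
        frac = (null.samples > -math.log(0.05)).mean()
        assert abs(frac - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / B)

    def test_addone_pvalue_bounds(self):
        null = ds.simulate_null_distribution(20, B=150, seed=1)
        assert null.pvalue(np.inf if False else 1e9) == pytest.approx(1 / 151)
        assert null.pvalue(-1.0) == 1.0
        for q in np.linspace(0, 15, 7):
            assert 1 / 151 <= null.pvalue(q) <= 1.0

    def test_windowed_null_deterministic_and_sane(self):
        n1 = simulate_windowed_null(40, 2, 2, B=150, seed=3)
        n2 = simulate_windowed_null(40, 2, 2, B=150, seed=3)
        np.testing.assert_array_equal(n1.samples, n2.samples)
        assert (n1.samples > 0).all()

    def test_small_B_rejected(self):
        with pytest.raises(ValidationError):
            ds.simulate_null_distribution(10, B=50, seed=0)


class TestCallSvrs:
    def test_flat_pvalues_yield_no_svrs(self):
        p = np.full(100, 0.5)
        pv = PositionalPValues("t", p)
        regions = ds.enumerate_candidate_regions(pv, 1, 100)
        null = ds.simulate_null_distribution(100, B=500, seed=7)
        res = ds.call_svrs(regions, null, n=100, pvals=pv)
        assert res.svrs == []

    def test_strong_block_yields_one_overlapping_svr(self):
        """p = 1e-6 on positions 11-20 on a flat background: one SVR
        overlapping at least 8 of the block positions."""
        p = np.full(100, 0.5)
        p[10:20] = 1e-6
        pv = PositionalPValues("t", p)
        regions = ds.enumerate_candidate_regions(pv, 1, 100)
        null = ds.simulate_null_distribution(100, B=500, seed=7)
        res = ds.call_svrs(regions, null, n=100, pvals=pv)
        assert len(res.svrs) == 1
        overlap = len(set(res.svrs[0].positions()) & set(range(11, 21)))
        assert overlap >= 8
        assert res.svr_pvalues[0] == pytest.approx(1 / 501)

    def test_overlapping_regions_keep_higher_q(self):
        null = ds.simulate_null_distribution(30, B=300, seed=2)
        r1 = ds.CandidateRegion("t", 5, 10, 50.0)
        r2 = ds.CandidateRegion("t", 8, 12, 40.0)
        r3 = ds.CandidateRegion("t", 20, 25, 45.0)
        res = ds.call_svrs([r1, r2, r3], null, n=30)
        assert [(r.start, r.end) for r in res.svrs] == [(5, 10), (20, 25)]

    def test_mismatched_null_length_rejected(self):
        null = ds.simulate_null_distribution(30, B=200, seed=2)
        regions = [ds.CandidateRegion("t", 1, 5, 3.0)]
        with pytest.raises(ValidationError):
            ds.call_svrs(regions, null, n=200)

    def test_called_svrs_nonoverlapping_and_significant(self, rng):
        p = rng.uniform(1e-8, 1.0, 80)
        pv = PositionalPValues("t", p)
        regions = ds.enumerate_candidate_regions(pv, 1, 80)
        null = ds.simulate_null_distribution(80, B=300, seed=4)
        res = ds.call_svrs(regions, null, n=80, pvals=pv)
        for i, a in enumerate(res.svrs):
            for b in res.svrs[i + 1 :]:
                assert not a.overlaps(b)
        assert all(pval <= res.alpha for pval in res.svr_pvalues)


class TestRankNucleotides:
    def make_result(self, p, svrs, n):
        pv = PositionalPValues("t", p)
        null = ds.simulate_null_distribution(n, B=150, seed=0)
        return ds.ScanResult("t", n, svrs, [0.01] * len(svrs), pv, null, 0.05)

    def test_fallback_is_ascending_positional_p(self):
        p = np.array([0.9, 0.1, 0.5, 0.3])
        order = ds.rank_nucleotides(self.make_result(p, [], 4))
        assert list(order) == [2, 4, 3, 1]

    def test_topk_equals_called_positions(self):
        p = np.full(10, 0.5)
        svrs = [ds.CandidateRegion("t", 3, 5, 9.0)]
        order = ds.rank_nucleotides(self.make_result(p, svrs, 10))
        assert set(order[:3]) == {3, 4, 5}

    def test_higher_q_svr_positions_rank_first(self):
        p = np.full(12, 0.5)
        svrs = [ds.CandidateRegion("t", 1, 3, 4.0), ds.CandidateRegion("t", 7, 9, 9.0)]
        order = ds.rank_nucleotides(self.make_result(p, svrs, 12))
        assert list(order[:3]) == [7, 8, 9]
        assert set(order[3:6]) == {1, 2, 3}


class TestScanDataset:
    def test_null_cache_shares_nulls_across_similar_lengths(self):
        cache = NullCache(1, 50, 150, seed=0, mode="uniform")
        a = cache.get(100)
        b = cache.get(101)
        assert a is b  # within the +-5% bin
        c = cache.get(150)
        assert c is not a

    def test_permutation_null_mode_runs(self, rng):
        a = [rng.random(30) for _ in range(3)]
        b = [rng.random(30) for _ in range(3)]
        res = ds.scan_dataset(make_dataset(a, b), B=100, seed=5,
                              null_mode="permutation", L_max=30)
        assert "tx1" in res

    def test_global_fwer_tightens_alpha(self, rng):
        profiles = []
        for tx in ("t1", "t2"):
            for cond, r in (("A", "a"), ("B", "b")):
                for i in range(2):
                    profiles.append(
                        ds.ReactivityProfile(tx, cond, f"{r}{i}", rng.random(40))
                    )
        dataset = ds.ReactivityDataset(profiles)
        res = ds.scan_dataset(dataset, B=150, seed=1, global_fwer=True, L_max=40)
        assert all(r.alpha == pytest.approx(0.025) for r in res.values())
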