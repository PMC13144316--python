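"""Statistical primitives against independent oracles and worked values."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import nnls as scipy_nnls
from scipy.stats import fisher_exact as scipy_fisher
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from stratomics.stats import (
    ContingencyTable2x2,
    bh_adjust,
    cosine_similarity,
    fisher_exact_two_sided,
    hypergeom_upper_tail,
    mann_whitney_u,
    nnls,
    wilcoxon_rank_sum,
)


def brute_force_fisher_p(a, b, c, d):
    """Exhaustive probability-mass two-sided p over tables with fixed margins."""
    N = a + b + c + d
    r1, K = a + b, a + c
    lo, hi = max(0, r1 - (N - K)), min(r1, K)

    def pmf(x):
        return (
            math.comb(K, x) * math.comb(N - K, r1 - x) / math.comb(N, r1)
        )

    p_obs = pmf(a)
    return min(1.0, sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-7)))


class TestFisher:
    @pytest.mark.parametrize(
        "table, p, odds",
        [
            ((5, 5, 5, 5), 1.0, 1.0),
            ((0, 17, 0, 689), 1.0, math.nan),
        ],
    )
    def test_worked_examples(self, table, p, odds):
        r = fisher_exact_two_sided(ContingencyTable2x2(*table))
        assert r.p_value == pytest.approx(p)
        if math.isnan(odds):
            assert math.isnan(r.odds_ratio)
        else:
            assert r.odds_ratio == pytest.approx(odds)

    def test_strongly_imbalanced_table(self):
        # 4/17 vs 17/689 mutated: the cross-product odds ratio is 2688/221
        r = fisher_exact_two_sided(ContingencyTable2x2(4, 13, 17, 672))
        assert r.odds_ratio == pytest.approx(2688 / 221)
        assert r.odds_ratio == pytest.approx(12.16, abs=0.005)
        assert r.p_value == pytest.approx(brute_force_fisher_p(4, 13, 17, 672), abs=1e-12)

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or c + d == 0:
                continue
            mine = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d)).p_value
            assert mine == pytest.approx(brute_force_fisher_p(a, b, c, d), abs=1e-10)
            assert mine == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], abs=1e-9)

    def test_infinite_and_undefined_odds(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(3, 0, 0, 5)).odds_ratio == math.inf
        assert math.isnan(fisher_exact_two_sided(ContingencyTable2x2(0, 3, 0, 5)).odds_ratio)

    def test_rejects_empty_group(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 5))


class TestBH:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05], [0.05]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    def test_matches_statsmodels_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            theirs = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(ours, theirs, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=100)
    def test_structural_properties(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


def exact_mw_reference(x, y):
    """Full-enumeration two-sided Mann-Whitney p (independent of the implementation)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([x, y])
    nx = len(x)
    mu = nx * len(y) / 2
    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        u = ranks[list(idx)].sum() - nx * (nx + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_complete_separation_small(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0
        assert r.p_value == pytest.approx(0.1)

    def test_identical_samples(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3], mode="normal").p_value == 1.0

    def test_all_tied_zero_variance(self):
        assert mann_whitney_u([1, 1], [1, 1]).p_value == 1.0

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(2)
        for nx in range(2, 6):
            for ny in range(2, 6):
                if nx + ny > 10:
                    continue
                x = rng.normal(size=nx)
                y = rng.normal(size=ny)
                mine = mann_whitney_u(x, y, mode="exact").p_value
                assert mine == pytest.approx(exact_mw_reference(x, y), abs=1e-12)

    def test_normal_mode_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = np.round(rng.normal(size=rng.integers(5, 30)), 1)  # induces ties
            y = np.round(rng.normal(0.3, size=rng.integers(5, 30)), 1)
            mine = mann_whitney_u(x, y, mode="normal").p_value
            ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=20), rng.normal(0.5, size=35)
        assert mann_whitney_u(x, y).p_value == pytest.approx(mann_whitney_u(y, x).p_value)

    def test_wilcoxon_is_alias(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 4.0, 6.0]
        a = mann_whitney_u(x, y)
        b = wilcoxon_rank_sum(x, y)
        assert (a.statistic, a.p_value) == (b.statistic, b.p_value)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestHypergeom:
    def test_closed_form_toy(self):
        assert hypergeom_upper_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_lower_support_is_one(self):
        assert hypergeom_upper_tail(10, 6, 7, max(0, 7 + 6 - 10)) == pytest.approx(1.0)

    def test_matches_brute_sum(self):
        for N in (8, 12, 25):
            for K in range(N + 1):
                for n in range(N + 1):
                    lo, hi = max(0, n + K - N), min(n, K)
                    k = (lo + hi) // 2
                    brute = sum(
                        math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                        for i in range(k, hi + 1)
                    )
                    assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(brute, abs=1e-12)

    def test_complement_sums_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            N = int(rng.integers(2, 50))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n + K - N), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            upper = hypergeom_upper_tail(N, K, n, k)
            lower = sum(
                math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
                for i in range(lo, k)
            )
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_rejects_out_of_support(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(10, 5, 5, 6)


class TestCosineAndNnls:
    def test_cosine_examples(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 1, 0], [1, 0, 0]) == pytest.approx(1 / math.sqrt(2))
        with pytest.raises(ValueError):
            cosine_similarity([0, 0], [1, 0])

    def test_exact_mixture_recovery(self):
        rng = np.random.default_rng(6)
        A = rng.random((96, 5))
        A /= A.sum(axis=0)
        b = 0.7 * A[:, 0] + 0.3 * A[:, 1]
        x = nnls(A, b)
        assert x[:2] == pytest.approx([0.7, 0.3], abs=1e-9)
        assert x[2:] == pytest.approx(np.zeros(3), abs=1e-9)

    def test_single_column_indicator(self):
        rng = np.random.default_rng(7)
        A = rng.random((20, 4))
        x = nnls(A, A[:, 2])
        assert x == pytest.approx([0, 0, 1, 0], abs=1e-9)

    def test_matches_scipy_objective(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            A = rng.random((30, rng.integers(2, 8)))
            b = rng.random(30)
            mine = nnls(A, b)
            ref, _ = scipy_nnls(A, b)
            assert np.linalg.norm(A @ mine - b) <= np.linalg.norm(A @ ref - b) + 1e-8
            # never better than unconstrained LS, never worse than clipped LS
            ls, *_ = np.linalg.lstsq(A, b, rcond=None)
            assert np.linalg.norm(A @ mine - b) >= np.linalg.norm(A @ ls - b) - 1e-12
            assert np.linalg.norm(A @ mine - b) <= np.linalg.norm(A @ np.clip(ls, 0, None) - b) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            nnls(np.ones((3, 2)), np.ones(4))
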