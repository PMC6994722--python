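"""Exact small-sample inference: oracle equivalence and the decision rule."""

from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats

from engramkit import inference


def brute_force_signed_rank_p(n: int, w: float) -> float:
    """Two-tailed p by enumerating all 2^n sign vectors over ranks 1..n."""
    ranks = np.arange(1, n + 1)
    hits = total = 0
    for signs in product((-1, 1), repeat=n):
        total += 1
        if abs(np.dot(signs, ranks)) >= abs(w):
            hits += 1
    return hits / total


def brute_force_u_p(m: int, n: int, u: float) -> float:
    """Two-tailed p by enumerating all C(m+n, m) group labelings."""
    mn = m * n
    u_star = min(u, mn - u)
    vals = range(m + n)
    hits = total = 0
    for comb in combinations(vals, m):
        s = set(comb)
        u_obs = sum(1 for a in comb for b in vals if b not in s and a > b)
        total += 1
        if u_obs <= u_star or u_obs >= mn - u_star:
            hits += 1
    return min(1.0, hits / total)


class TestWilcoxonExact:
    def test_matches_brute_force_for_all_small_n(self):
        """DP-computed exact p equals 2^n enumeration for every (n, W)."""
        for n in range(1, 11):
            m_tot = n * (n + 1) // 2
            for w in range(-m_tot, m_tot + 1, 2 if m_tot % 2 == 0 else 1):
                if (w - m_tot) % 2 != 0:
                    continue
                res = inference.wilcoxon_exact(n=n, w=w)
                assert res.p_two_tailed == pytest.approx(
                    brute_force_signed_rank_p(n, w), abs=1e-12
                ), (n, w)

    def test_null_distribution_sums_to_one_and_is_symmetric(self):
        for n in (4, 7, 12):
            support, counts = inference.signed_rank_null(range(1, n + 1))
            assert counts.sum() > 0
            m_tot = n * (n + 1) / 2
            w_support = 2 * support - m_tot
            # symmetric about 0 on the signed-rank scale
            assert np.array_equal(counts, counts[::-1])
            assert w_support[0] == -m_tot and w_support[-1] == m_tot

    def test_p_monotone_in_abs_w(self):
        for n in (6, 7):
            m_tot = n * (n + 1) // 2
            ws = [w for w in range(0, m_tot + 1) if (w - m_tot) % 2 == 0]
            ps = [inference.wilcoxon_exact(n=n, w=w).p_two_tailed for w in ws]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_from_differences_matches_scipy_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            d = rng.normal(0.5, 1.0, size=8)
            d = d[d != 0]
            if np.unique(np.abs(d)).size < d.size:
                continue
            ours = inference.wilcoxon_exact(d)
            ref = stats.wilcoxon(d, mode="exact")
            assert ours.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_removed_and_w_at_center_clamps_to_one(self):
        res = inference.wilcoxon_exact([1.0, -1.5, 2.0, 0.0, -2.5])
        assert res.n == (4,)
        assert inference.wilcoxon_exact(n=7, w=0).p_two_tailed == 1.0

    def test_ties_flagged_not_exact(self):
        res = inference.wilcoxon_exact([1.0, 1.0, -1.0, 2.0, 3.0])
        assert not res.exact
        assert "midrank" in res.note

    def test_unattainable_w_rejected(self):
        with pytest.raises(ValueError):
            inference.wilcoxon_exact(n=7, w=27)  # parity violation
        with pytest.raises(ValueError):
            inference.wilcoxon_exact(n=5, w=16)  # |W| > n(n+1)/2

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            inference.wilcoxon_exact([0.0, 0.0])


class TestMannWhitneyExact:
    def test_matches_brute_force_for_all_small_sizes(self):
        """DP p equals the C(m+n, m)-labeling oracle for all U."""
        for m in range(1, 7):
            for n in range(m, 13 - m):
                for u in range(m * n + 1):
                    res = inference.mannwhitney_exact(m=m, n=n, u=u)
                    assert res.p_two_tailed == pytest.approx(
                        brute_force_u_p(m, n, u), abs=1e-12
                    ), (m, n, u)

    def test_null_symmetric_about_half_mn(self):
        for m, n in ((7, 6), (5, 5), (3, 8)):
            counts = inference.mann_whitney_null(m, n)
            assert np.array_equal(counts, counts[::-1])
            from math import comb
            assert counts.sum() == comb(m + n, m)

    def test_u_zero_small_groups(self):
        # complete separation of 3 vs 3: one labeling per tail out of 20
        res = inference.mannwhitney_exact(m=3, n=3, u=0)
        assert res.p_two_tailed == pytest.approx(0.1)

    def test_p_monotone_in_distance_from_center(self):
        m, n = 6, 5
        mn = m * n
        ps = [inference.mannwhitney_exact(m=m, n=n, u=u).p_two_tailed
              for u in range(mn // 2 + 1)]
        assert all(a <= b for a, b in zip(ps, ps[1:]))

    def test_from_data_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(0, 1, size=6)
            y = rng.normal(0.8, 1, size=7)
            ours = inference.mannwhitney_exact(x, y)
            ref = stats.mannwhitneyu(x, y, method="exact")
            assert ours.p_two_tailed == pytest.approx(ref.pvalue, abs=1e-12)

    def test_statistic_symmetric_under_swap(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        a = inference.mannwhitney_exact(x, y)
        b = inference.mannwhitney_exact(y, x)
        assert a.statistic == b.statistic
        assert a.p_two_tailed == b.p_two_tailed

    def test_tied_data_flagged_approximate(self):
        res = inference.mannwhitney_exact([1, 2, 2, 3], [2, 4, 5, 6])
        assert not res.exact

    def test_empty_group_error(self):
        with pytest.raises(ValueError):
            inference.mannwhitney_exact([], [1.0, 2.0])


class TestTTests:
    def test_identical_groups_t_zero_p_one(self):
        res = inference.t_tests([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=False)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_two_tailed == pytest.approx(1.0)

    def test_pooled_degrees_of_freedom(self):
        """Groups of 16 and 13 give the classical df = 27."""
        rng = np.random.default_rng(3)
        res = inference.t_tests(rng.normal(size=16), rng.normal(size=13),
                                paired=False)
        assert res.df == 27

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        rejections = 0
        reps = 10_000
        for _ in range(reps):
            x = rng.standard_normal(8)
            y = rng.standard_normal(8)
            if inference.t_tests(x, y, paired=False).p_two_tailed < 0.05:
                rejections += 1
        assert 0.04 <= rejections / reps <= 0.06

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(ValueError):
            inference.t_tests([1, 2, 3], [1, 2], paired=True)

    def test_zero_pooled_variance_unequal_means_error(self):
        with pytest.raises(ValueError):
            inference.t_tests([1.0, 1.0], [2.0, 2.0], paired=False)


class TestDecisionRule:
    def test_mapping(self):
        assert inference.choose_test("paired", False) == "wilcoxon_signed_rank"
        assert inference.choose_test("paired", True) == "paired_t"
        assert inference.choose_test("independent", True) == "unpaired_t"
        assert inference.choose_test("independent", False) == "mann_whitney"
        assert inference.choose_test("correlation", True) == "pearson"

    def test_gate_passes_gaussian_at_roughly_one_minus_alpha(self):
        rng = np.random.default_rng(5)
        passes = sum(
            inference.normality_gate(rng.standard_normal(50))
            for _ in range(1000)
        )
        assert 0.90 <= passes / 1000 <= 0.98

    def test_gate_rejects_two_valued_sample(self):
        rng = np.random.default_rng(6)
        sample = rng.choice([0.0, 1.0], size=40)
        assert not inference.normality_gate(sample)

    def test_gate_constant_vector_is_non_normal(self):
        assert not inference.normality_gate([2.0, 2.0, 2.0, 2.0])

    def test_gate_small_sample_error(self):
        with pytest.raises(ValueError):
            inference.normality_gate([1.0, 2.0])

    def test_compare_dispatches_to_rank_test_for_skewed_paired_data(self):
        rng = np.random.default_rng(7)
        x = rng.lognormal(0, 1.5, size=12)
        y = x + rng.lognormal(0.2, 1.5, size=12)
        res = inference.compare(x, y, "paired")
        assert res.method in ("wilcoxon_signed_rank", "paired_t")

    def test_pearson_on_colinear_points(self):
        res = inference.pearson_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.statistic == pytest.approx(1.0)
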