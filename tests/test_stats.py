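"""Nonparametric battery: closed forms, exact enumeration oracles, calibration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sst

from vlpoca import (
    friedman_ranks,
    kruskal_dunn,
    mann_whitney,
    ranksum_tests,
    snk_posthoc_ranks,
    wilcoxon_signed_rank,
)


class TestFriedman:
    def test_perfect_ordering_closed_form(self):
        # n=3 subjects all ranking the k=3 conditions identically: R=(3,6,9)
        X = np.tile([1.0, 2.0, 3.0], (3, 1))
        res = friedman_ranks(X)
        assert res.statistic == pytest.approx(6.0)

    def test_all_equal_cells_give_zero_statistic(self):
        res = friedman_ranks(np.ones((5, 3)))
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(12, 4))
        mine = friedman_ranks(X)
        ref = sst.friedmanchisquare(*X.T)
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.pvalue == pytest.approx(ref.pvalue)

    def test_rejects_missing_cells_and_small_designs(self):
        with pytest.raises(ValueError, match="complete blocks"):
            friedman_ranks(np.array([[1.0, np.nan, 2.0], [1, 2, 3]]))
        with pytest.raises(ValueError):
            friedman_ranks(np.ones((1, 3)))
        with pytest.raises(ValueError):
            friedman_ranks(np.ones((5, 2)))


class TestSnk:
    def test_identical_conditions_yield_no_significant_pairs(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 4))
        table = snk_posthoc_ranks(X + X.mean())  # no real shift
        assert table["significant"].sum() <= 1  # chance findings only

    def test_single_shifted_condition_flagged_against_all_others(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 4))
        X[:, 2] += 100.0
        table = snk_posthoc_ranks(X, labels=list("abcd"))
        sig = table[table["significant"]]
        assert all("c" in (r["a"], r["b"]) for _, r in sig.iterrows())
        assert len(sig) == 3

    def test_studentized_range_quantiles_match_reference_table(self):
        # classic q_{0.05}(p, inf) values
        from vlpoca.stats import _q_crit

        assert _q_crit(0.05, 2) == pytest.approx(2.772, abs=0.01)
        assert _q_crit(0.05, 3) == pytest.approx(3.314, abs=0.01)
        assert _q_crit(0.05, 4) == pytest.approx(3.633, abs=0.01)

    def test_nonsignificant_span_blocks_inner_comparisons(self):
        X = np.tile([1.0, 1.0, 1.0, 1.0], (10, 1))
        rng = np.random.default_rng(3)
        X += rng.normal(0, 1e-3, X.shape)
        table = snk_posthoc_ranks(X)
        widest = table[table["span"] == 4].iloc[0]
        assert not widest["significant"]
        inner = table[table["span"] < 4]
        assert (~inner["significant"]).all()
        assert inner["blocked"].all()


class TestWilcoxon:
    def brute_force_p(self, d, alternative="two-sided"):
        """Enumerate all sign patterns of |d| ranks (exact null)."""
        ranks = sst.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        n = len(d)
        ws = [
            sum(r for r, s in zip(ranks, signs) if s)
            for signs in itertools.product([False, True], repeat=n)
        ]
        ws = np.asarray(ws)
        p_le = np.mean(ws <= w_obs + 1e-9)
        p_ge = np.mean(ws >= w_obs - 1e-9)
        if alternative == "less":
            return p_le
        if alternative == "greater":
            return p_ge
        return min(1.0, 2 * min(p_le, p_ge))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("alternative", ["two-sided", "less", "greater"])
    def test_exact_pvalues_match_enumeration(self, seed, alternative):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=8)
        y = x + rng.normal(0.3, 1.0, size=8)
        res = wilcoxon_signed_rank(x, y, alternative=alternative)
        assert res.pvalue == pytest.approx(self.brute_force_p(x - y, alternative))

    def test_uniform_shift_gives_minimal_one_sided_p(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=10)
        res = wilcoxon_signed_rank(x, x + 1.0, alternative="less")
        assert res.pvalue == pytest.approx(1 / 2**10)

    def test_single_nonzero_pair(self):
        res = wilcoxon_signed_rank([1.0], [0.5])
        assert res.pvalue == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.pvalue == 1.0
        assert res.details["degenerate"]

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=15)
        y = x + rng.normal(0.4, 1, size=15)
        res = wilcoxon_signed_rank(x, y)
        ref = sst.wilcoxon(x, y, mode="exact")
        assert res.pvalue == pytest.approx(ref.pvalue)


class TestMannWhitney:
    def brute_force_p(self, x, y):
        N, m = len(x) + len(y), len(x)
        ranks = sst.rankdata(np.concatenate([x, y]))
        r_obs = ranks[:m].sum()
        sums = [sum(c) for c in itertools.combinations(ranks, m)]
        sums = np.asarray(sums)
        p_le = np.mean(sums <= r_obs + 1e-9)
        p_ge = np.mean(sums >= r_obs - 1e-9)
        return min(1.0, 2 * min(p_le, p_ge))

    def test_complete_separation_small_n(self):
        res = mann_whitney([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(0.1)  # 2 / C(6,3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_pvalues_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=6)
        y = rng.normal(0.5, 1.0, size=7)
        res = mann_whitney(x, y)
        assert res.details["method"] == "exact"
        assert res.pvalue == pytest.approx(self.brute_force_p(x, y))

    def test_matches_scipy_asymptotic_with_ties(self):
        rng = np.random.default_rng(6)
        x = np.round(rng.normal(size=40), 1)
        y = np.round(rng.normal(0.3, 1, size=35), 1)
        res = mann_whitney(x, y)
        ref = sst.mannwhitneyu(x, y, method="asymptotic")
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])
        with pytest.raises(ValueError):
            ranksum_tests([[1.0], [2.0], [3.0]], variant="mann_whitney")


class TestKruskalDunn:
    def test_identical_groups_near_zero_h_no_dunn_hits(self):
        g = [np.arange(10.0)] * 3
        res = kruskal_dunn(g)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert not res.pairwise["significant"].any()

    def test_matches_scipy_h(self):
        rng = np.random.default_rng(7)
        g = [rng.normal(size=20), rng.normal(size=25), rng.normal(1, 1, size=15)]
        res = kruskal_dunn(g)
        ref = sst.kruskal(*g)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)

    def test_dunn_flags_exactly_the_shifted_group_pairs(self):
        rng = np.random.default_rng(8)
        g = [rng.normal(size=20), rng.normal(size=20), rng.normal(10, 1, size=20)]
        res = kruskal_dunn(g, labels=list("ABC"))
        sig = res.pairwise[res.pairwise["significant"]]
        assert set(map(tuple, sig[["a", "b"]].to_numpy())) == {("A", "C"), ("B", "C")}

    def test_bonferroni_adjustment_inflates_pvalues(self):
        rng = np.random.default_rng(9)
        g = [rng.normal(size=15) for _ in range(3)]
        raw = kruskal_dunn(g).pairwise["pvalue"].to_numpy()
        adj = kruskal_dunn(g, adjust="bonferroni").pairwise["pvalue"].to_numpy()
        assert np.all(adj >= raw - 1e-12)


class TestInvariances:
    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 500))
    def test_rank_tests_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(8, 3))
        x, y = rng.normal(size=9), rng.normal(size=9)
        a, b = rng.normal(size=7), rng.normal(0.5, 1, size=8)
        f = lambda v: np.exp(v)  # strictly increasing

        assert friedman_ranks(X).pvalue == pytest.approx(friedman_ranks(f(X)).pvalue)
        # signed-rank: any odd increasing transform of the differences
        d = x - y
        ref = wilcoxon_signed_rank(d)
        cubed = wilcoxon_signed_rank(d**3)
        assert cubed.statistic == ref.statistic
        assert cubed.pvalue == pytest.approx(ref.pvalue)
        assert mann_whitney(a, b).pvalue == pytest.approx(mann_whitney(f(a), f(b)).pvalue)
        g = [rng.normal(size=6) for _ in range(3)]
        assert kruskal_dunn(g).pvalue == pytest.approx(kruskal_dunn([f(v) for v in g]).pvalue)
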