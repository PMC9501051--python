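"""Statistical primitives against independent oracles and hand calculations."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from crossres.stats import (
    fisher_exact_2x2,
    km_estimate,
    kruskal_wallis,
    log_rank_test,
    pearson_matrix,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


class TestWilcoxon:
    def test_exact_small_sample(self):
        """{1,2,3} vs {4,5,6}: 2 of the 20 rank assignments are as extreme."""
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert res.method == "wilcoxon-exact"
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.p_value == 1.0

    def test_exact_matches_enumeration(self):
        """Exact p equals direct enumeration over all rank partitions."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            res = wilcoxon_rank_sum(x, y)
            pooled = np.concatenate([x, y])
            ranks = sps.rankdata(pooled)
            u_obs = ranks[:4].sum() - 4 * 5 / 2
            n = len(pooled)
            us = []
            for combo in itertools.combinations(range(n), 4):
                u = ranks[list(combo)].sum() - 4 * 5 / 2
                us.append(u)
            us = np.asarray(us)
            center = 4 * 5 / 2
            p_enum = np.mean(np.abs(us - center) >= abs(u_obs - center) - 1e-12)
            assert res.p_value == pytest.approx(p_enum, abs=1e-12)

    def test_asymptotic_matches_hand_formula(self):
        """Tie/continuity-corrected normal approximation, reproduced by hand."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.integers(0, 10, 30).astype(float)
            y = (rng.integers(0, 10, 25) + 1).astype(float)
            res = wilcoxon_rank_sum(x, y)
            n1, n2 = len(x), len(y)
            n = n1 + n2
            ranks = sps.rankdata(np.concatenate([x, y]))
            u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            ubig = max(u1, n1 * n2 - u1)
            _, t = np.unique(np.concatenate([x, y]), return_counts=True)
            var = n1 * n2 / 12 * ((n + 1) - ((t**3 - t).sum()) / (n * (n - 1)))
            z = (ubig - n1 * n2 / 2 - 0.5) / math.sqrt(var)
            p_hand = min(2 * sps.norm.sf(z), 1.0)
            if u1 == n1 * n2 / 2:
                p_hand = 1.0
            assert res.p_value == pytest.approx(p_hand, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])


# ---------------------------------------------------------------------------
# Fisher's exact test


class TestFisher:
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((0, 34, 2, 8), 0.048),   # SERD, CR vs PD, full TR cohort
            ((0, 25, 2, 5), 0.042),   # SERD, CR vs PD, RPPA subset
            ((1, 24, 4, 3), 0.004),   # death, CR vs PD, RPPA subset
            ((27, 7, 4, 6), 0.043),   # stage I-II vs III-IV by response
        ],
    )
    def test_reference_contingency_tables(self, table, printed):
        """Printed baseline-table p-values from their 2x2 counts."""
        p = fisher_exact_2x2(*table).p_value
        assert round(p, 3) == printed

    def test_degenerate_margin_gives_p_one(self):
        assert fisher_exact_2x2(0, 5, 0, 7).p_value == 1.0
        assert fisher_exact_2x2(0, 0, 3, 4).p_value == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 25, size=4)
            mine = fisher_exact_2x2(a, b, c, d).p_value
            ref = sps.fisher_exact([[a, b], [c, d]]).pvalue
            assert mine == pytest.approx(ref, abs=1e-10)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


# ---------------------------------------------------------------------------
# Kruskal-Wallis


class TestKruskalWallis:
    def test_two_groups_close_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = rng.normal(0.3, 1, size=70)
        p_kw = kruskal_wallis([x, y]).p_value
        p_w = wilcoxon_rank_sum(x, y).p_value
        assert abs(p_kw - p_w) < 0.01

    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([[1, 1, 1], [1, 1], [1, 1, 1, 1]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_hand_h_statistic(self):
        """Tie-free H from the rank-sum formula."""
        groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 9.0], [6.0, 7.0, 8.0]]
        res = kruskal_wallis(groups)
        ranks = sps.rankdata(np.concatenate(groups))
        n = 9
        r_sums = [ranks[:3].sum(), ranks[3:6].sum(), ranks[6:].sum()]
        h = 12 / (n * (n + 1)) * sum(r**2 / 3 for r in r_sums) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.p_value == pytest.approx(sps.chi2.sf(h, 2), abs=1e-10)


# ---------------------------------------------------------------------------
# Kaplan-Meier


class TestKaplanMeier:
    def test_all_censored_stays_at_one(self):
        curve = km_estimate([5, 8, 13], [False, False, False])
        assert curve.event_times.size == 0
        assert curve.censor_marks.size == 3

    def test_no_censoring_matches_empirical_survival(self):
        """Without censoring S(t) is the fraction still event-free after t."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            times = rng.integers(1, 30, size=25).astype(float)
            curve = km_estimate(times, np.ones(25, dtype=bool))
            for t in np.unique(times):
                assert curve.survival_at(t) == pytest.approx(
                    np.mean(times > t), abs=1e-12
                )

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [True, True, True])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0], abs=1e-12)
        assert list(curve.at_risk) == [3, 2, 1]

    def test_order_invariance(self):
        times = [9.0, 1.0, 4.0, 4.0, 7.0]
        events = [True, False, True, True, False]
        a = km_estimate(times, events)
        order = [2, 0, 4, 1, 3]
        b = km_estimate([times[i] for i in order], [events[i] for i in order])
        assert a.survival == pytest.approx(b.survival)
        assert np.array_equal(a.event_times, b.event_times)


# ---------------------------------------------------------------------------
# log-rank


class TestLogRank:
    def test_identical_groups_give_chi2_zero(self):
        times = [3.0, 5.0, 8.0, 12.0] * 2
        events = [True, False, True, True] * 2
        groups = [0] * 4 + [1] * 4
        res = log_rank_test(times, events, groups)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_matches_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 120))
            times = rng.exponential(10, n)
            events = rng.random(n) < 0.7
            g = rng.random(n) < 0.5
            if g.all() or not g.any():
                continue
            mine = log_rank_test(times, events, g)
            ref = ll_logrank(times[g], times[~g], events[g], events[~g])
            assert mine.chi_square == pytest.approx(ref.test_statistic, abs=1e-6)
            assert mine.p_value == pytest.approx(ref.p_value, abs=1e-6)

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, 40)
        events = rng.random(40) < 0.6
        g = rng.random(40) < 0.4
        a = log_rank_test(times, events, g)
        b = log_rank_test(times, events, ~g)
        assert a.chi_square == pytest.approx(b.chi_square, abs=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            log_rank_test([1, 2], [True, True], [0, 0])


# ---------------------------------------------------------------------------
# Pearson correlation matrix


class TestPearsonMatrix:
    def test_self_and_negated(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        mat = np.column_stack([x, -x])
        corr = pearson_matrix(mat, ["f", "neg"])
        assert corr.r[0, 0] == pytest.approx(1.0)
        assert corr.r[0, 1] == pytest.approx(-1.0)
        assert corr.p[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_scipy_pairwise(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(size=(40, 4))
        mat[3, 1] = np.nan
        corr = pearson_matrix(mat)
        for i in range(4):
            for j in range(i + 1, 4):
                ok = ~(np.isnan(mat[:, i]) | np.isnan(mat[:, j]))
                r_ref, p_ref = sps.pearsonr(mat[ok, i], mat[ok, j])
                assert corr.r[i, j] == pytest.approx(r_ref, abs=1e-10)
                assert corr.p[i, j] == pytest.approx(p_ref, abs=1e-10)

    def test_constant_feature_recorded_missing(self):
        mat = np.column_stack([np.ones(10), np.arange(10.0)])
        corr = pearson_matrix(mat)
        assert np.isnan(corr.r[0, 1])
        assert np.isnan(corr.r[0, 0])
        assert corr.r[1, 1] == 1.0

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        corr = pearson_matrix(rng.normal(size=(25, 5)))
        assert np.allclose(corr.r, corr.r.T, equal_nan=True)
        assert np.allclose(np.diag(corr.r), 1.0)
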