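"""Exact-test oracles and the ROC / logistic / PCA utilities.

The Fisher, rank-sum and binomial implementations are checked against
brute-force enumeration on all small inputs, and the approximate rank-sum
path against its exact counterpart.
"""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from gliotex import cohort_stats as cs


# --- enumeration oracles ---------------------------------------------------

def fisher_oracle(table):
    """Enumerate all tables with the observed margins using exact rational
    hypergeometric probabilities; sum those no more probable than observed."""
    (a, b), (c, d) = table
    r0, c0, n = a + b, a + c, a + b + c + d
    denom = comb(n, c0)

    def prob(x):
        return comb(r0, x) * comb(n - r0, c0 - x)  # integer numerator

    obs = prob(a)
    total = sum(p for x in range(max(0, c0 - (n - r0)), min(r0, c0) + 1)
                if (p := prob(x)) <= obs)
    return total / denom


def ranksum_oracle(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    p = 2 * min(np.mean(us <= u_obs), np.mean(us >= u_obs))
    return min(1.0, p)


def binom_tail_oracle(k, n, p0):
    return sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in range(k, n + 1))


def all_small_tables(max_total):
    for n in range(2, max_total + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    t = [[a, b], [c, d]]
                    if min(a + b, c + d, a + c, b + d) > 0:
                        yield t


class TestFisher:
    def test_table1_genotype_counts(self):
        # genotype-by-cohort table: 46/13 mutant/wild in training,
        # 14/6 in validation
        assert cs.fisher_exact_2x2([[46, 13], [14, 6]]) == pytest.approx(
            0.548, abs=5e-4)

    def test_minimal_tables(self):
        assert cs.fisher_exact_2x2([[1, 0], [0, 1]]) == pytest.approx(1.0)
        assert cs.fisher_exact_2x2([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_matches_enumeration_on_all_small_tables(self):
        for t in all_small_tables(12):
            assert cs.fisher_exact_2x2(t) == pytest.approx(
                fisher_oracle(t), rel=1e-6), t

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.integers(1, 15, size=(2, 2))
            assert cs.fisher_exact_2x2(t) == pytest.approx(
                cs.fisher_exact_2x2(t[:, ::-1]))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cs.fisher_exact_2x2([[0, 0], [3, 4]])


class TestRankSum:
    def test_tiny_exact_value(self):
        assert cs.wilcoxon_rank_sum([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_near_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert cs.wilcoxon_rank_sum(x, x) >= 0.99

    def test_matches_enumeration_small_untied(self):
        rng = np.random.default_rng(1)
        for n1, n2 in [(1, 3), (2, 4), (3, 3), (4, 5), (5, 6), (6, 6)]:
            x = rng.standard_normal(n1)
            y = rng.standard_normal(n2) + rng.uniform(-1, 1)
            assert cs.wilcoxon_rank_sum(x, y) == pytest.approx(
                ranksum_oracle(x, y), rel=1e-9)

    def test_exact_vs_approximate_agreement(self):
        """Exact enumeration and the corrected normal approximation agree
        within 0.02 on random 10 + 10 samples."""
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10) + rng.uniform(-0.5, 0.5)
            exact = ranksum_oracle(x, y)
            approx = stats.mannwhitneyu(x, y, alternative="two-sided",
                                        method="asymptotic").pvalue
            assert abs(exact - min(1.0, approx)) < 0.02

    def test_group_swap_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(8), rng.standard_normal(11)
        assert cs.wilcoxon_rank_sum(x, y) == pytest.approx(
            cs.wilcoxon_rank_sum(y, x))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.wilcoxon_rank_sum([], [1.0])


class TestWelch:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0]
        assert cs.welch_t(x, x) == pytest.approx(1.0)

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(20)
        assert cs.welch_t(x, x + 10.0) < 1e-6

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(12)
        y = 2.0 * rng.standard_normal(20) + 0.7
        assert cs.welch_t(x, y) == pytest.approx(
            stats.ttest_ind(x, y, equal_var=False).pvalue)


class TestBinomialTail:
    def test_whole_support(self):
        assert cs.binomial_exact_greater(0, 20, 0.3) == 1.0

    def test_single_term(self):
        assert cs.binomial_exact_greater(20, 20, 0.5) == pytest.approx(2.0**-20)

    def test_top_two_terms(self):
        expected = comb(20, 19) * 0.7**19 * 0.3 + 0.7**20
        assert cs.binomial_exact_greater(19, 20, 0.70) == pytest.approx(expected)

    def test_matches_enumeration_small(self):
        for n in range(1, 13):
            for k in range(n + 1):
                for p0 in (0.2, 0.5, 0.77):
                    assert cs.binomial_exact_greater(k, n, p0) == pytest.approx(
                        binom_tail_oracle(k, n, p0), rel=1e-10)

    def test_probability_limits(self):
        assert cs.binomial_exact_greater(0, 5, 0.0) == 1.0
        assert cs.binomial_exact_greater(3, 5, 0.0) == 0.0
        assert cs.binomial_exact_greater(5, 5, 1.0) == 1.0


class TestRoc:
    def test_perfect_and_degenerate(self):
        assert cs.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]).auc == 1.0
        assert cs.roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]).auc == 0.5

    def test_hand_counted_pairs(self):
        roc = cs.roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert roc.auc == pytest.approx(0.75)

    def test_curve_shape(self):
        roc = cs.roc_auc([0.2, 0.6, 0.4, 0.9, 0.1], [0, 1, 0, 1, 1])
        assert roc.fpr[0] == 0.0 and roc.tpr[0] == 0.0
        assert roc.fpr[-1] == 1.0 and roc.tpr[-1] == 1.0
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        s = np.round(rng.random(50), 1)  # force ties
        assert cs.roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cs.roc_auc([0.1, 0.9], [1, 1])


class TestLogistic:
    def test_constant_predictor(self):
        beta, auc, flags = cs.logistic_univariate([2.0] * 10, [0, 1] * 5)
        assert beta[1] == 0.0 and auc == 0.5 and "constant_x" in flags

    def test_complete_separation_flagged(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        beta, auc, flags = cs.logistic_univariate(y.astype(float), y)
        assert "separation" in flags
        assert np.all(np.isfinite(beta))
        assert auc == 1.0

    def test_auc_matches_closed_form_for_gaussian_classes(self):
        """Two unit-variance normal classes one SD apart have AUC
        Phi(1/sqrt(2)) ~ 0.760."""
        rng = np.random.default_rng(7)
        aucs = []
        for _ in range(10):
            x = np.concatenate([rng.standard_normal(500),
                                rng.standard_normal(500) + 1])
            y = np.repeat([0, 1], 500)
            _, auc, _ = cs.logistic_univariate(x, y)
            aucs.append(auc)
        assert np.mean(aucs) == pytest.approx(stats.norm.cdf(1 / np.sqrt(2)), abs=0.03)

    def test_coefficients_match_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        x = rng.standard_normal(200)
        y = (rng.random(200) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(int)
        beta, _, flags = cs.logistic_univariate(x, y)
        assert not flags
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0).params
        assert np.allclose(beta, ref, atol=1e-6)

    def test_auc_equals_roc_of_linear_predictor(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        y = (x + rng.standard_normal(100) > 0).astype(int)
        beta, auc, _ = cs.logistic_univariate(x, y)
        assert auc == pytest.approx(cs.roc_auc(x * np.sign(beta[1]), y).auc)


class TestPca:
    def test_collinear_data_one_component(self):
        x = np.random.default_rng(10).standard_normal(30)
        X = np.column_stack([x, 2 * x])
        scores, frac = cs.pca_scores(X, 1)
        assert frac[0] == pytest.approx(1.0)

    def test_fraction_properties(self):
        X = np.random.default_rng(11).standard_normal((40, 5))
        _, frac = cs.pca_scores(X, 4)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-12

    def test_full_rank_scores_are_isometric(self):
        X = np.random.default_rng(12).standard_normal((15, 4))
        scores, _ = cs.pca_scores(X, 4)
        Xc = X - X.mean(0)
        d_orig = np.linalg.norm(Xc[:, None] - Xc[None, :], axis=2)
        d_new = np.linalg.norm(scores[:, None] - scores[None, :], axis=2)
        assert np.allclose(d_orig, d_new)

    def test_rank_overflow_rejected(self):
        X = np.zeros((5, 3))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValueError):
            cs.pca_scores(X, 2)
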