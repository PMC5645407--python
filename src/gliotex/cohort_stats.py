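"""Cohort-level statistics for the radiogenomic analysis.

Exact small-sample tests (Fisher 2x2, rank-sum, binomial tail against the
no-information rate), Welch's t, ROC/AUC by pair counting, univariate
logistic regression of genotype on tumor size, and a PCA of selected
features.  Conventions follow mainstream exact-test implementations: the
two-sided Fisher p-value is the point-probability method, the rank-sum test
is exact for small untied samples and normal-approximated (tie- and
continuity-corrected) otherwise, and AUC ties count one half.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RocCurve", "fisher_exact_2x2", "wilcoxon_rank_sum", "welch_t",
           "binomial_exact_greater", "roc_auc", "logistic_univariate", "pca_scores"]

_EXACT_RANKSUM_MAX_N = 20


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table, point-probability method.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed one (relative
    slack 1e-7); probabilities are handled in log space.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a 2x2 table of non-negative integers")
    r0, r1 = t.sum(axis=1)
    c0, c1 = t.sum(axis=0)
    if min(r0, r1, c0, c1) == 0:
        raise ValueError("all margins must be positive")
    n = t.sum()
    # support of the (0,0) cell given the margins
    lo = max(0, c0 - r1)
    hi = min(r0, c0)
    xs = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(xs, n, r0, c0)
    obs = stats.hypergeom.logpmf(t[0, 0], n, r0, c0)
    keep = logp <= obs + np.log1p(1e-7)
    return float(min(1.0, np.exp(logp[keep]).sum()))


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p; exact when n1+n2 <= 20 with no ties, else corrected normal."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if combined.size <= _EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(1.0, res.pvalue))


def welch_t(x, y) -> float:
    """Two-sided Welch t-test p-value (Satterthwaite degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        if np.mean(x) == np.mean(y):
            return 1.0
        raise ValueError("zero variance in both samples")
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def binomial_exact_greater(successes: int, n: int, p0: float) -> float:
    """P(X >= successes) for X ~ Binomial(n, p0) — the no-information-rate test."""
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    if p0 <= 0.0:
        return 1.0 if successes == 0 else 0.0
    if p0 >= 1.0:
        return 1.0
    return float(stats.binom.sf(successes - 1, n, p0))


@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(probabilities, labels) -> RocCurve:
    """ROC curve and AUC with the Mann-Whitney pair-counting estimator.

    ``labels`` are 1/True for positives.  Tied positive/negative scores count
    0.5; the curve is swept at midpoints between consecutive unique scores.
    """
    s = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both classes to compute a ROC curve")
    ranks = stats.rankdata(s)  # midranks handle ties -> 0.5 per tied pair
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    uniq = np.unique(s)
    mids = (uniq[1:] + uniq[:-1]) / 2.0
    cuts = np.concatenate([[np.inf], mids[::-1], [-np.inf]])
    fpr, tpr = [], []
    for c in cuts:
        pred = s >= c
        tpr.append(np.sum(pred & y) / n_pos)
        fpr.append(np.sum(pred & ~y) / n_neg)
    return RocCurve(fpr=np.array(fpr), tpr=np.array(tpr), auc=float(auc))


def logistic_univariate(x, labels, max_iter: int = 50, tol: float = 1e-8):
    """Univariate logistic regression (IRLS) of a binary label on one predictor.

    Returns ``(intercept, slope), auc, flags`` where flags may contain
    ``"constant_x"`` or ``"separation"``.  Complete separation is detected by
    a diverging linear predictor and resolved by a ridge fallback
    (lambda = 1e-6) so finite coefficients are always returned.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels).astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes")
    flags: list[str] = []
    if np.ptp(x) == 0:
        beta = np.array([np.log(y.mean() / (1 - y.mean())), 0.0])
        flags.append("constant_x")
        return beta, 0.5, flags
    X = np.column_stack([np.ones_like(x), x])

    def irls(ridge: float) -> tuple[np.ndarray, bool]:
        beta = np.zeros(2)
        for _ in range(max_iter):
            eta = X @ beta
            if np.max(np.abs(eta)) > 30.0:
                return beta, True  # diverging linear predictor
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            H = X.T @ (w[:, None] * X) + 2.0 * ridge * np.eye(2)
            g = X.T @ (y - p) - 2.0 * ridge * beta
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                return beta, False
        return beta, False

    beta, separated = irls(0.0)
    if separated:
        flags.append("separation")
        beta, _ = irls(1e-6)
    eta = X @ beta
    auc = roc_auc(1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500))), y > 0.5).auc
    return beta, float(auc), flags


def pca_scores(feature_matrix, n_components: int):
    """Principal-component scores and explained-variance fractions.

    Columns are centered; components come from the singular decomposition
    with each component's sign fixed so its largest-magnitude loading is
    positive.  Explained-variance fractions are relative to total variance.
    """
    X = np.asarray(feature_matrix, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size and s[0] > 0 else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    for j in range(n_components):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = U[:, :n_components] * s[:n_components]
    total = np.sum(s ** 2)
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, frac
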