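"""Two-marker combination and ROC discrimination analysis.

The two splice-variant expression levels are combined into a single score
by a maximum-likelihood logistic regression on their log2 values; the score
is the fitted linear predictor. Discrimination is summarized by the
empirical ROC curve and its AUC, computed with the rank (Mann-Whitney)
formula with half-credit for ties, and a 95% confidence interval from the
DeLong covariance estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve

__all__ = ["RocResult", "SeparationWarning", "combine_markers", "roc_auc", "delong_ci"]


class SeparationWarning(UserWarning):
    """The two classes are (quasi-)completely separated in marker space."""


@dataclass
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    thresholds: np.ndarray
    fpr: np.ndarray  # 1 - specificity, nondecreasing
    tpr: np.ndarray  # sensitivity, nondecreasing

    def __post_init__(self):
        assert 0 <= self.ci_low <= self.auc <= self.ci_high <= 1


def combine_markers(
    long_expr: np.ndarray, short_expr: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Per-sample score from a two-covariate logistic model on log2 levels.

    On complete separation the maximum-likelihood fit diverges; the scores
    along the diverging direction are still returned (they rank samples
    correctly, which is all ROC analysis needs) and a SeparationWarning is
    emitted.
    """
    long_expr = np.asarray(long_expr, float)
    short_expr = np.asarray(short_expr, float)
    y = np.asarray(labels, int)
    if (long_expr <= 0).any() or (short_expr <= 0).any():
        raise ValueError("expression values must be strictly positive")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 samples per class")
    X = sm.add_constant(np.column_stack([np.log2(long_expr), np.log2(short_expr)]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            params = fit.params
            separated = not fit.mle_retvals.get("converged", True)
        except Exception:
            params, separated = None, True
    if params is None or not np.isfinite(params).all():
        # Fisher discriminant direction as the diverging-direction score
        mu1 = X[y == 1, 1:].mean(axis=0)
        mu0 = X[y == 0, 1:].mean(axis=0)
        cov = np.cov(X[:, 1:].T) + 1e-9 * np.eye(2)
        w = np.linalg.solve(cov, mu1 - mu0)
        warnings.warn("complete separation; returning discriminant scores", SeparationWarning)
        return X[:, 1:] @ w
    scores = X @ params
    if separated or np.abs(params[1:]).max() > 1e3:
        warnings.warn("(quasi-)complete separation in logistic fit", SeparationWarning)
    return scores


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney rank AUC with half-credit for ties."""
    ranks = stats.rankdata(scores)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def delong_ci(scores: np.ndarray, labels: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """(auc, ci_low, ci_high) via DeLong's structural-components variance."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    # placement values (structural components)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return auc, float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1))


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> RocResult:
    """Empirical ROC over all thresholds with rank-formula AUC and a 95%
    DeLong confidence interval."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc, lo, hi = delong_ci(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    # DeLong point estimate equals the rank AUC; keep the rank formula as
    # the reported value
    auc_rank = _rank_auc(scores, labels)
    assert abs(auc - auc_rank) < 1e-12
    lo = min(lo, auc_rank)
    hi = max(hi, auc_rank)
    return RocResult(auc_rank, lo, hi, n_pos, n_neg, thr, fpr, tpr)
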