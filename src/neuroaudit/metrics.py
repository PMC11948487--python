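"""Performance metrics, chance levels and the corrected resampled t-test.

Accuracy does not handle class imbalance; balanced accuracy and the
rank-based AUC are provided for that case.  For small evaluation sets a
point estimate of chance (1/C under uniform priors) is not enough: the
smallest accuracy that exceeds chance at significance alpha is governed by
the binomial upper tail, and :func:`chance_level` reports that bound.

Cross-validation folds share training data and are therefore positively
correlated; a naive paired t-test on fold-wise metric differences is
anti-conservative.  :func:`corrected_ttest` inflates the variance of the
mean difference to account for that correlation, approximated as rho = 1/k,
mapping rho into

    Var(dbar) = sigma_d^2 * (1/k + rho * (k-1)/k)

with the classical test/train-ratio correction (c = n2/n1) available as an
alternative.  Degrees of freedom are k - 1 and the confidence interval uses
t quantiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .exceptions import ArgumentError

__all__ = [
    "accuracy",
    "balanced_accuracy",
    "auc_binary",
    "ChanceEstimate",
    "chance_level",
    "CorrectedTTestResult",
    "corrected_ttest",
    "ttest_from_summary",
    "compute_metric",
]


def accuracy(predicted, truth) -> float:
    """Fraction of exact matches."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ArgumentError("predicted and truth must have the same length")
    if truth.size == 0:
        raise ArgumentError("empty inputs")
    return float(np.mean(predicted == truth))


def balanced_accuracy(predicted, truth) -> float:
    """Unweighted mean of per-class recalls.

    Classes absent from ``truth`` are dropped with a warning (they carry no
    recall information on this evaluation set).
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ArgumentError("predicted and truth must have the same length")
    classes = np.unique(truth)
    if classes.size == 0:
        raise ArgumentError("empty inputs")
    recalls = [np.mean(predicted[truth == c] == c) for c in classes]
    return float(np.mean(recalls))


def auc_binary(scores, truth) -> float:
    """Rank-based AUC: P(random positive outscores random negative).

    Midrank tie handling; invariant under strictly monotone transforms of
    the scores.  Requires both classes present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    if len(np.unique(truth)) != 2:
        raise ArgumentError("AUC requires exactly two classes present in truth")
    return float(roc_auc_score(truth, scores))


@dataclass
class ChanceEstimate:
    """Theoretical chance level and its finite-sample significance bound."""

    theoretical: float  # best naive-guess accuracy (max prior; 1/C uniform)
    analytic_bound: float  # smallest a/n with binomial tail prob <= alpha
    n: int
    alpha: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"chance {self.theoretical:.3f}; accuracy must exceed "
            f"{self.analytic_bound:.3f} to beat chance at alpha={self.alpha} (n={self.n})"
        )


def chance_level(n: int, class_priors, alpha: float = 0.05) -> ChanceEstimate:
    """Analytic chance level for accuracy on an evaluation set of size n.

    ``theoretical`` is the accuracy of always guessing the most probable
    class (max prior; 1/C for uniform priors).  ``analytic_bound`` is the
    smallest a/n such that P(X >= a) <= alpha for X ~ Binomial(n,
    theoretical): the least observed accuracy that is significantly above
    chance.  The bound decreases toward the theoretical level as n grows.
    """
    priors = np.asarray(class_priors, dtype=float)
    if n < 1:
        raise ArgumentError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ArgumentError("alpha must lie in (0, 1)")
    if np.any(priors < 0) or not np.isclose(priors.sum(), 1.0):
        raise ArgumentError("class priors must be non-negative and sum to 1")
    p0 = float(priors.max())
    tail = stats.binom.sf(np.arange(n + 1) - 1, n, p0)  # P(X >= a), a = 0..n
    ok = np.flatnonzero(tail <= alpha)
    bound = float(ok[0]) / n if ok.size else float("inf")
    return ChanceEstimate(theoretical=p0, analytic_bound=bound, n=n, alpha=alpha)


@dataclass
class CorrectedTTestResult:
    mean_diff: float
    sd_diff: float
    k: int
    rho: float | None
    correction: float  # the additive variance term c
    se: float
    t: float
    df: int
    p: float
    ci_low: float
    ci_high: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"corrected resampled t-test: dbar={self.mean_diff:.4f} "
            f"[{self.ci_low:.4f}, {self.ci_high:.4f}], t={self.t:.3f}, "
            f"df={self.df}, p={self.p:.4f}"
        )


def corrected_ttest(
    fold_diffs,
    rho_mode: str = "one_over_k",
    test_train_ratio: float | None = None,
    conf_level: float = 0.95,
) -> CorrectedTTestResult:
    """Corrected resampled t-test on fold-wise metric differences.

    Parameters
    ----------
    fold_diffs : array-like, length k
        Per-fold difference between two procedures evaluated on the same
        folds.
    rho_mode : {"one_over_k", "test_train_ratio", "none"}
        How to correct for the fold correlation: the rho = 1/k
        approximation (default), the classical n2/n1 test/train-ratio term,
        or no correction (classical one-sample t-test; for cross-checks).
    """
    d = np.asarray(fold_diffs, dtype=float)
    k = d.size
    if k < 2:
        raise ArgumentError("need at least 2 fold differences")
    dbar = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ArgumentError("degenerate variance: all fold differences identical")
    if rho_mode == "one_over_k":
        rho = 1.0 / k
        c = rho * (k - 1) / k
    elif rho_mode == "test_train_ratio":
        if test_train_ratio is None:
            test_train_ratio = 1.0 / (k - 1)  # equal-sized folds
        rho = None
        c = float(test_train_ratio)
    elif rho_mode == "none":
        rho = 0.0
        c = 0.0
    else:
        raise ArgumentError(f"unknown rho_mode {rho_mode!r}")
    se = sd * np.sqrt(1.0 / k + c)
    df = k - 1
    t = dbar / se
    p = float(2 * stats.t.sf(abs(t), df))
    tq = stats.t.ppf(0.5 + conf_level / 2, df)
    return CorrectedTTestResult(
        mean_diff=dbar, sd_diff=sd, k=k, rho=rho, correction=c, se=float(se),
        t=float(t), df=df, p=p, ci_low=float(dbar - tq * se),
        ci_high=float(dbar + tq * se),
    )


def ttest_from_summary(mean_diff: float, ci_low: float, ci_high: float, df: int):
    """Recover (SE, t, p) from a reported mean difference and its 95% CI.

    Useful to audit published comparisons where only the mean difference and
    a t-based confidence interval are printed.  A mildly asymmetric interval
    (rounding) is tolerated with a warning, using the mean half-width.
    """
    if not (ci_low < mean_diff < ci_high):
        raise ArgumentError("mean_diff must lie strictly inside the interval")
    if df < 1:
        raise ArgumentError("df must be >= 1")
    lo_half = mean_diff - ci_low
    hi_half = ci_high - mean_diff
    if not np.isclose(lo_half, hi_half, rtol=0.05):
        warnings.warn("confidence interval not symmetric; using mean half-width")
    tq = stats.t.ppf(0.975, df)
    se = (ci_high - ci_low) / (2 * tq)
    t = mean_diff / se
    p = float(2 * stats.t.sf(abs(t), df))
    return float(se), float(t), p


def compute_metric(name: str, truth, predicted=None, scores=None) -> float:
    """Dispatch a metric by config name (accuracy | balanced_accuracy | auc)."""
    if name == "accuracy":
        return accuracy(predicted, truth)
    if name == "balanced_accuracy":
        return balanced_accuracy(predicted, truth)
    if name == "auc":
        if scores is None:
            raise ArgumentError("AUC requires scores")
        return auc_binary(scores, truth)
    raise ArgumentError(f"unknown metric {name!r}")
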