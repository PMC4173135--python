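"""Scoring-function assessment: ROC/AUC, ECDFs, quantile and optimal cutoffs.

AUC is computed from the Mann-Whitney rank statistic (ties credit 1/2),
which equals the trapezoidal area under the ROC curve built by a
descending-score threshold sweep.

The optimal-cutoff utility maximizes Youden's J = TPR - FPR over the
observed scores.  Continuous likeness scores are meant for ranking, not
qualitative classification; any single threshold is discouraged for
qualitative use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RocResult", "roc_auc", "cumulative_curve", "quantile_cutoffs", "optimal_cutoff"]


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _check_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes (labels 0 and 1) must be present")
    return scores, labels


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC for binary labels (1 = active/positive).

    The curve starts at (0, 0), ends at (1, 1), and steps at each
    distinct score threshold in descending order.  The AUC is the
    Mann-Whitney probability that a random positive outscores a random
    negative, with tied pairs contributing 1/2.
    """
    scores, labels = _check_labels(scores, labels)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos

    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]

    # collapse tied scores into single thresholds
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    idx_last = np.r_[np.nonzero(distinct)[0][1:] - 1, s_sorted.size - 1]
    tp = np.cumsum(l_sorted)[idx_last]
    fp = np.cumsum(1 - l_sorted)[idx_last]

    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[idx_last]]

    # midranks give the tie-aware Mann-Whitney statistic
    ranks = _midranks(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def cumulative_curve(scores):
    """Empirical CDF: (sorted scores, cumulative fraction) arrays.

    The fraction at a score s is the proportion of scores <= s, so the
    median is readable where the fraction first reaches 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sequence")
    s = np.sort(scores)
    frac = np.arange(1, s.size + 1) / s.size
    return s, frac


def quantile_cutoffs(scores, probs=(0.25, 0.5, 0.75)) -> dict:
    """Empirical quantiles with linear interpolation between order statistics."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score sequence")
    return {float(p): float(np.quantile(scores, p)) for p in probs}


def optimal_cutoff(scores, labels):
    """Threshold among observed scores maximizing Youden's J = TPR - FPR.

    Ties break toward the smaller threshold.  Returns ``(threshold, j)``.
    A single cutoff on a continuous likeness score is discouraged for
    qualitative use; this utility exists for exploratory comparison only.
    """
    scores, labels = _check_labels(scores, labels)
    roc = roc_auc(scores, labels)
    j = roc.tpr - roc.fpr
    # skip the leading (inf, 0, 0) anchor; argmax favors the first (largest
    # threshold) maximum, so scan from the smallest threshold instead
    best_idx = len(j) - 1 - int(np.argmax(j[:0:-1]))
    return float(roc.thresholds[best_idx]), float(j[best_idx])
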