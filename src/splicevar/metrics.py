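"""Classification metrics and the one-sided Welch's t-test.

Metric conventions:

* probabilities are binarized by a strict ``> threshold`` rule at 0.5, so a
  probability of exactly 0.5 is called negative;
* AUPRC uses the step-wise (threshold-enumeration, average-precision style)
  integration rather than trapezoidal interpolation of the PR curve, which
  is known to be optimistic;
* AUROC equals the Mann-Whitney pair statistic, ties counted 1/2;
* undefined precision (no positive predictions) is reported as 0.0, and an
  MCC with a zero denominator as 0.0, so imbalanced-subset sweeps never
  produce NaNs.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score


def binarize(probs, threshold: float = 0.5) -> np.ndarray:
    """Convert probabilities to 0/1 labels with a strict ``>`` rule."""
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p > threshold).astype(int)


def confusion_metrics(pred_labels, true_labels) -> tuple[float, float, float]:
    """Precision, recall and Matthews correlation from 0/1 label vectors."""
    pred = np.asarray(pred_labels, dtype=int)
    true = np.asarray(true_labels, dtype=int)
    if pred.shape != true.shape:
        raise ValueError(
            f"length mismatch: {pred.shape[0]} predictions vs "
            f"{true.shape[0]} truths"
        )
    tp = float(np.sum((pred == 1) & (true == 1)))
    fp = float(np.sum((pred == 1) & (true == 0)))
    fn = float(np.sum((pred == 0) & (true == 1)))
    tn = float(np.sum((pred == 0) & (true == 0)))
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision reported as 0",
                      RuntimeWarning, stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / denom
    return precision, recall, mcc


def _check_two_class(true: np.ndarray) -> None:
    if len(np.unique(true)) < 2:
        raise ValueError("both classes must be present to compute a curve area")


def auprc(probs, true_labels) -> float:
    """Area under the precision-recall curve (step-wise integration)."""
    true = np.asarray(true_labels, dtype=int)
    _check_two_class(true)
    return float(average_precision_score(true, np.asarray(probs, dtype=float)))


def auroc(probs, true_labels) -> float:
    """Area under the ROC curve (= Mann-Whitney pair statistic)."""
    true = np.asarray(true_labels, dtype=int)
    _check_two_class(true)
    return float(roc_auc_score(true, np.asarray(probs, dtype=float)))


def welch_t_one_sided(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Welch's unequal-variance t-test with a one-sided alternative.

    ``alternative="greater"`` tests whether the mean of ``x`` exceeds the
    mean of ``y``; degrees of freedom follow Welch-Satterthwaite.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
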