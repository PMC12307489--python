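"""Classification metrics: accuracy, Cohen's kappa, across-subject SD.

Kappa is chance-corrected agreement computed from the confusion matrix:
``kappa = (P0 - Pe) / (1 - Pe)`` where ``P0`` is the observed agreement
(accuracy) and ``Pe = sum_i x_i * P_i / N**2`` the agreement expected
from the row (true) and column (predicted) marginals.  The SD metric is
the sample standard deviation (divide by N - 1) of per-subject
accuracies, a stability measure across subjects.
"""

from __future__ import annotations

import numpy as np

__all__ = ["confusion_matrix", "kappa", "accuracy", "accuracy_sd", "cross_entropy"]


def confusion_matrix(y_true, y_pred, n_classes: int = 4) -> np.ndarray:
    """Counts indexed (true class, predicted class)."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm) / n)


def kappa(cm: np.ndarray) -> float:
    """Cohen's kappa from a (true x predicted) confusion matrix."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    p0 = np.trace(cm) / n
    pe = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / n**2
    if pe >= 1.0 - 1e-12:
        if p0 >= 1.0 - 1e-12:
            return 1.0  # all mass on one agreeing cell
        raise ValueError("kappa undefined: chance agreement is 1 with P0 < 1")
    return float((p0 - pe) / (1.0 - pe))


def accuracy_sd(per_subject_acc) -> float:
    """Sample standard deviation of per-subject accuracies."""
    acc = np.asarray(per_subject_acc, dtype=np.float64)
    if acc.size < 2:
        raise ValueError("SD needs at least two subjects")
    return float(np.std(acc, ddof=1))


def cross_entropy(probabilities, true_label: int, epsilon: float = 1e-12) -> float:
    """Categorical cross-entropy -sum_i y_i log(p_i) with one-hot truth.

    The predicted probability of the true class is clamped below by
    ``epsilon`` so a zero prediction yields a large finite loss.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("expected a single probability vector")
    if not (0 <= true_label < p.size):
        raise ValueError("true_label outside class range")
    if p.min() < -1e-9 or abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("probabilities must form a distribution")
    return float(-np.log(max(p[true_label], epsilon)))
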