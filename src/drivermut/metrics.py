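"""Binary-classification metrics computed from a confusion matrix.

All metrics are stored as proportions on [0, 1] (MCC on [-1, 1]); rendering
as percentages is a presentation concern (``as_percentages``). Driver
mutations are the positive class throughout.
"""

from __future__ import annotations

import math

import numpy as np

from .types import ConfusionMatrix, ValidationError

#: Metric names in report order.
METRICS = ("precision", "recall", "accuracy", "f_measure", "mcc")


def metrics_from_confusion(cm: ConfusionMatrix) -> dict[str, float]:
    """Precision, recall, accuracy, F-measure and MCC from raw counts.

    Degenerate cases follow the usual conventions: a zero MCC denominator
    yields MCC = 0; a classifier that never predicts positive (tp+fp = 0)
    has *undefined* precision, reported as NaN rather than 0 so that a
    degenerate model is visible in reports.
    """
    if cm.total <= 0:
        raise ValidationError("confusion matrix is empty")
    tp, fp, tn, fn = (float(cm.tp), float(cm.fp), float(cm.tn), float(cm.fn))

    recall = tp / (tp + fn) if tp + fn > 0 else math.nan
    precision = tp / (tp + fp) if tp + fp > 0 else math.nan
    accuracy = (tp + tn) / (tp + tn + fn + fp)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f_measure = math.nan
    else:
        f_measure = 2 * precision * recall / (precision + recall)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / math.sqrt(denom)

    return {
        "precision": precision,
        "recall": recall,
        "accuracy": accuracy,
        "f_measure": f_measure,
        "mcc": mcc,
    }


def as_percentages(metrics: dict[str, float]) -> dict[str, float]:
    """Render proportion-valued metrics x100; MCC stays on its native scale."""
    out = {}
    for name, value in metrics.items():
        if name in ("precision", "recall", "accuracy", "f_measure") and not math.isnan(
            value
        ):
            out[name] = 100.0 * value
        else:
            out[name] = value
    return out


def roc_area(scores, labels, positive) -> float:
    """Area under the ROC curve by the rank statistic.

    Equals the probability that a uniformly drawn positive sample outscores a
    uniformly drawn negative one, with ties counted half (the Mann-Whitney U
    form; identical to trapezoidal AUC).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC area needs both classes present")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks handle ties
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
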