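"""Binary-classification evaluation: ACC, PR, RE, F1, MCC and rank-based AUC."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(labels_true, labels_pred) -> ConfusionCounts:
    """Confusion counts for 0/1 label vectors of equal length."""
    yt = np.asarray(labels_true).astype(int)
    yp = np.asarray(labels_pred).astype(int)
    if yt.shape != yp.shape:
        raise ValueError("label vectors differ in length")
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("%s has zero denominator; defined as 0", what)
        return 0.0
    return num / den


def scores(counts: ConfusionCounts) -> dict:
    """ACC, PR, RE, F1 and MCC from confusion counts.

    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)). Any score
    with a zero denominator is defined as 0 (warned).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    mcc_den = math.sqrt(float(tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return {
        "ACC": _safe_div(tp + tn, counts.total, "ACC"),
        "PR": _safe_div(tp, tp + fp, "PR"),
        "RE": _safe_div(tp, tp + fn, "RE"),
        "F1": _safe_div(2 * tp, 2 * tp + fp + fn, "F1"),
        "MCC": _safe_div(tp * tn - fn * fp, mcc_den, "MCC"),
    }


def auc(labels_true, probabilities) -> float:
    """Rank-based (Mann-Whitney) ROC AUC with midrank tie handling."""
    y = np.asarray(labels_true).astype(int)
    p = np.asarray(probabilities, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    r = rankdata(p)
    return (float(r[y == 1].sum()) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
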