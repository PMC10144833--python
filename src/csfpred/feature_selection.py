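"""Two-stage feature selection.

Stage one removes irrelevant dimensions: a two-sided Wilcoxon rank-sum test
per feature against the class label, Benjamini-Hochberg q-values, and a
q <= alpha (default 0.05) retention rule. Stage two removes redundant
dimensions by recursive feature elimination ranked by the stage-one q-values:
at each iteration the ``step`` (default 20) surviving columns with the
largest q are dropped, a surrogate classifier is retrained on the training
partition, and validation F1/AUC are recorded. The optimal subset is the
smallest feature count whose validation score is within ``epsilon`` of the
curve maximum. Because the q-ranking is fixed, the elimination order is
deterministic; ties in q are broken by column order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import metrics
from .pu_ensemble import MLPClassifier, classify

logger = logging.getLogger(__name__)


def ranksum_pvalues(values: np.ndarray, labels) -> np.ndarray:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p per column.

    Normal approximation with tie and continuity correction. A column that is
    constant across both groups carries no information and gets p = 1.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.isnan(x).any():
        raise ValueError("missing values present; impute before testing")
    g1, g0 = x[y == 1], x[y == 0]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("both label groups must be non-empty")
    p = np.ones(x.shape[1])
    varying = x.ptp(axis=0) > 0 if hasattr(x, "ptp") else np.ptp(x, axis=0) > 0
    for j in np.flatnonzero(varying):
        p[j] = mannwhitneyu(g1[:, j], g0[:, j], alternative="two-sided",
                            method="asymptotic", use_continuity=True).pvalue
    return p


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def stage1_filter(q: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Retain a column iff its q-value is <= alpha."""
    return np.asarray(q, dtype=float) <= alpha


@dataclass
class SelectionResult:
    column_names: list
    p_values: np.ndarray
    q_values: np.ndarray
    stage1_mask: np.ndarray
    elimination_order: list = field(default_factory=list)  # dropped groups, in order
    curve: list = field(default_factory=list)  # (n_features, F1, AUC)
    selected_columns: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "column_names": list(self.column_names),
            "p_values": np.asarray(self.p_values).tolist(),
            "q_values": np.asarray(self.q_values).tolist(),
            "stage1_mask": np.asarray(self.stage1_mask).astype(bool).tolist(),
            "elimination_order": self.elimination_order,
            "curve": [[int(n), float(f1), float(a)] for n, f1, a in self.curve],
            "selected_columns": list(self.selected_columns),
        })

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        return cls(d["column_names"], np.array(d["p_values"]), np.array(d["q_values"]),
                   np.array(d["stage1_mask"], dtype=bool), d["elimination_order"],
                   [tuple(e) for e in d["curve"]], d["selected_columns"])


def default_model_factory(seed: int) -> MLPClassifier:
    """Fast single-network surrogate with the ensemble's architecture."""
    return MLPClassifier(seed=seed)


def _evaluate(model, x_val, y_val, threshold=0.5):
    p = model.predict_proba(x_val)
    f1 = metrics.scores(metrics.confusion(y_val, classify(p, threshold)))["F1"]
    return f1, metrics.auc(y_val, p)


def rfe(x_train: np.ndarray, y_train, x_val: np.ndarray, y_val,
        columns: list, importance: np.ndarray, step: int = 20,
        model_factory=default_model_factory, seed: int = 0) -> tuple[list, list]:
    """Recursive feature elimination ranked by fixed q-value importance.

    Returns (elimination_order, curve). The curve holds one
    (n_features, F1, AUC) entry for the initial full set and one per
    iteration; the surrogate model is retrained from a fixed seed each time so
    the curve is reproducible. The final partial iteration drops down to a
    floor of one column.
    """
    importance = np.asarray(importance, dtype=float)
    if len(importance) != len(columns):
        raise ValueError("importance must cover every surviving column")
    # stable ordering: worst (largest q) last, ties broken by column index
    order = np.argsort(-importance, kind="stable")  # descending q
    surviving = list(range(len(columns)))
    elimination_order: list = []
    curve: list = []
    rank = {j: r for r, j in enumerate(order)}  # low rank = large q = drop first
    while True:
        model = model_factory(seed)
        model.fit(x_train[:, surviving], np.asarray(y_train))
        f1, auc_ = _evaluate(model, x_val[:, surviving], np.asarray(y_val))
        curve.append((len(surviving), f1, auc_))
        if len(surviving) <= 1:
            break
        n_drop = min(step, len(surviving) - 1)
        by_badness = sorted(surviving, key=lambda j: rank[j])
        drop = sorted(by_badness[:n_drop])
        elimination_order.append([columns[j] for j in drop])
        surviving = [j for j in surviving if j not in set(drop)]
    return elimination_order, curve


def select_optimal(curve: list, epsilon: float = 0.005, criterion: str = "auc") -> int:
    """Smallest feature count whose validation score is within ``epsilon`` of
    the curve maximum; returns that feature count."""
    if not curve:
        raise ValueError("empty curve")
    idx = {"f1": 1, "auc": 2}[criterion]
    best = max(e[idx] for e in curve)
    eligible = [e[0] for e in curve if e[idx] >= best - epsilon]
    return min(eligible)


def two_stage_select(x_train: np.ndarray, y_train, x_val: np.ndarray, y_val,
                     columns: list, alpha: float = 0.05, step: int = 20,
                     epsilon: float = 0.005, criterion: str = "auc",
                     model_factory=default_model_factory, seed: int = 0) -> SelectionResult:
    """Full two-stage procedure; returns a populated :class:`SelectionResult`.

    The selected columns are the ``select_optimal`` feature count's worth of
    stage-one survivors with the smallest q-values (equivalently, the set
    surviving RFE at that curve point), in original column order.
    """
    columns = list(columns)
    p = ranksum_pvalues(x_train, y_train)
    q = bh_qvalues(p)
    mask = stage1_filter(q, alpha)
    kept = np.flatnonzero(mask)
    logger.info("stage 1: removed %d of %d dimensions (q > %g), %d remain",
                len(columns) - len(kept), len(columns), alpha, len(kept))
    if len(kept) == 0:
        return SelectionResult(columns, p, q, mask)
    kept_cols = [columns[j] for j in kept]
    elim, curve = rfe(x_train[:, kept], y_train, x_val[:, kept], y_val,
                      kept_cols, q[kept], step=step,
                      model_factory=model_factory, seed=seed)
    n_opt = select_optimal(curve, epsilon, criterion)
    surviving = set(kept_cols)
    for group in elim:
        if len(surviving) == n_opt:
            break
        surviving -= set(group)
    selected = [c for c in kept_cols if c in surviving]
    assert len(selected) == n_opt, (len(selected), n_opt)
    return SelectionResult(columns, p, q, mask, elim, curve, selected)
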