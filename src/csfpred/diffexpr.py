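"""Differential expression and biomarker-candidate intersection.

Case/control expression matrices (FPKM-like, genes x samples) are transformed
with log2(x+1) and quantile-normalized across samples; per-gene significance
comes from the Wilcoxon rank-sum test with Benjamini-Hochberg q-values, and
per-gene fold change FC_i = sum_j c_ij / sum_j n_ij is computed on the raw
scale. A gene is called up-regulated when q <= alpha and FC > fc_cutoff,
down-regulated when q <= alpha and FC < 1/fc_cutoff (defaults alpha 0.05,
fc_cutoff 2). Gene calls are mapped to proteins and intersected with the
predicted secreted-protein probabilities to yield biomarker candidates:
differentially expressed proteins that are predicted secreted (probability
> 0.5) but not already experimentally verified.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .feature_selection import bh_qvalues, ranksum_pvalues

logger = logging.getLogger(__name__)

CASE, CONTROL = "case", "control"


def _split_groups(matrix: pd.DataFrame, groups) -> tuple[np.ndarray, np.ndarray]:
    g = pd.Series(groups, index=matrix.columns) if not isinstance(groups, pd.Series) \
        else groups.reindex(matrix.columns)
    bad = set(g.unique()) - {CASE, CONTROL}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    case = matrix.columns[g == CASE]
    ctrl = matrix.columns[g == CONTROL]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("both case and control groups must be non-empty")
    return case, ctrl


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log2(x+1); rejects negative expression values."""
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    return np.log2(matrix + 1.0)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile normalization across samples (columns).

    Every sample's sorted values are replaced by the cross-sample means of the
    sorted values; tied values receive the mean of the pooled quantiles
    (midrank interpolation). Deterministic stand-in for the normalization step
    usually delegated to expression-analysis toolchains.
    """
    x = matrix.to_numpy(dtype=float)
    mean_sorted = np.sort(x, axis=0).mean(axis=1)
    n = x.shape[0]
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j])  # midranks for ties
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def identity_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """No-op normalization (pluggable alternative)."""
    return matrix


def fold_change(matrix: pd.DataFrame, groups) -> pd.Series:
    """Per-gene fold change: sum of case values over sum of control values,
    on the raw (untransformed) scale. Control sum 0 gives +inf (case sum > 0)
    or 1 (both sums 0)."""
    case, ctrl = _split_groups(matrix, groups)
    c = matrix[case].sum(axis=1).to_numpy(dtype=float)
    n = matrix[ctrl].sum(axis=1).to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = c / n
    fc[(n == 0) & (c > 0)] = np.inf
    fc[(n == 0) & (c == 0)] = 1.0
    if (n == 0).any():
        logger.warning("%d genes have zero control sum; FC flagged", int((n == 0).sum()))
    return pd.Series(fc, index=matrix.index, name="FC")


def de_call(q: np.ndarray, fc: np.ndarray, alpha: float = 0.05,
            fc_cutoff: float = 2.0) -> np.ndarray:
    """Regulation status per gene: 'up' iff q <= alpha and FC > fc_cutoff,
    'down' iff q <= alpha and FC < 1/fc_cutoff, else 'unchanged'."""
    q = np.asarray(q, dtype=float)
    fc = np.asarray(fc, dtype=float)
    status = np.full(len(q), "unchanged", dtype=object)
    status[(q <= alpha) & (fc > fc_cutoff)] = "up"
    status[(q <= alpha) & (fc < 1.0 / fc_cutoff)] = "down"
    return status


def de_analysis(matrix: pd.DataFrame, groups, alpha: float = 0.05,
                fc_cutoff: float = 2.0, normalize=quantile_normalize) -> pd.DataFrame:
    """Full differential-expression analysis of an FPKM-like matrix.

    Rank-sum p and BH q are computed on the log2(x+1), normalized values;
    fold change on the raw scale. Returns a DataFrame indexed by gene with
    columns p_value, q_value, FC, status.
    """
    case, ctrl = _split_groups(matrix, groups)
    transformed = normalize(log_transform(matrix))
    labels = np.concatenate([np.ones(len(case)), np.zeros(len(ctrl))])
    values = transformed[list(case) + list(ctrl)].to_numpy().T  # samples x genes
    p = ranksum_pvalues(values, labels)
    q = bh_qvalues(p)
    fc = fold_change(matrix, groups)
    return pd.DataFrame({
        "p_value": p, "q_value": q, "FC": fc.to_numpy(),
        "status": de_call(q, fc.to_numpy(), alpha, fc_cutoff),
    }, index=matrix.index)


def map_genes_to_proteins(de_table: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Propagate gene regulation calls to proteins through a gene->protein map.

    ``mapping`` has two columns (gene id, protein accession); many-to-many is
    allowed. A protein inheriting conflicting directions (up via one gene,
    down via another) is ambiguous and excluded with a warning. Unmapped genes
    are dropped (count logged). Returns a DataFrame indexed by protein with
    columns status, FC, q_value (FC/q from the most significant contributing
    gene).
    """
    if mapping.shape[1] != 2:
        raise ValueError("mapping must have exactly two columns: gene, protein")
    m = mapping.copy()
    m.columns = ["gene", "protein"]
    de = de_table[de_table["status"] != "unchanged"]
    unmapped = set(de.index) - set(m["gene"])
    if unmapped:
        logger.info("%d differentially expressed genes have no protein mapping", len(unmapped))
    joined = m.merge(de, left_on="gene", right_index=True, how="inner")
    if joined.empty:
        return pd.DataFrame(columns=["status", "FC", "q_value"])
    rows = {}
    ambiguous = []
    for protein, grp in joined.groupby("protein"):
        statuses = set(grp["status"])
        if len(statuses) > 1:
            ambiguous.append(protein)
            continue
        best = grp.sort_values("q_value", kind="stable").iloc[0]
        rows[protein] = (best["status"], best["FC"], best["q_value"])
    if ambiguous:
        logger.warning("%d proteins with conflicting gene directions excluded", len(ambiguous))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["status", "FC", "q_value"])
    out.index.name = "protein"
    return out.sort_index()


def intersect_biomarkers(protein_status: pd.DataFrame, predictions: pd.Series,
                         verified: set, threshold: float = 0.5) -> pd.DataFrame:
    """Partition differentially expressed proteins into biomarker categories.

    verified_CSF: in the experimentally verified set (overrides prediction);
    predicted_candidate: predicted probability > threshold and not verified —
    these are the potential biomarkers; not_CSF: the rest. Returns a DataFrame
    indexed by protein accession with columns FC, probability, q_value,
    status, category, sorted by descending probability.
    """
    verified = set(verified)
    cats, probs = [], []
    for protein in protein_status.index:
        p = predictions.get(protein, np.nan) if hasattr(predictions, "get") else np.nan
        if protein in verified:
            cat = "verified_CSF"
        elif not np.isnan(p) and p > threshold:
            cat = "predicted_candidate"
        else:
            if np.isnan(p):
                logger.warning("protein %s has no prediction; categorized not_CSF", protein)
            cat = "not_CSF"
        cats.append(cat)
        probs.append(p)
    out = protein_status.copy()
    out["probability"] = probs
    out["category"] = cats
    out = out[["FC", "probability", "q_value", "status", "category"]]
    return out.sort_values("probability", ascending=False, kind="stable")
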