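"""Evaluation metrics and differential-expression utilities.

F1 is computed with respect to the minor (rare) population; AUC-ROC uses
the Mann–Whitney formulation (ties count half), so it equals the
probability that a random minor cell outscores a random major cell.
Marker detection runs a two-sided Wilcoxon rank-sum test per gene with
Benjamini–Hochberg correction per comparison family; a gene qualifies as a
cluster marker only if it is significantly up-regulated, at the fold-change
cutoff, against every other cluster.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

from .matrix import ProcessedMatrix


@dataclass
class ConfusionMatrix:
    """Binary confusion counts w.r.t. the minor class."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_flags(
    predicted: np.ndarray, actual: np.ndarray
) -> ConfusionMatrix:
    """Confusion matrix of boolean predictions vs boolean minor labels."""
    predicted = np.asarray(predicted, dtype=bool)
    actual = np.asarray(actual, dtype=bool)
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must share shape")
    return ConfusionMatrix(
        tp=int((predicted & actual).sum()),
        fp=int((predicted & ~actual).sum()),
        fn=int((~predicted & actual).sum()),
        tn=int((~predicted & ~actual).sum()),
    )


def f1_score(cm: ConfusionMatrix) -> float:
    """Harmonic mean of precision and recall for the minor class.

    Degenerate cases (no predicted positives, no actual positives, or
    tp = 0) return 0 with a warning rather than raising.
    """
    if cm.tp + cm.fp == 0 or cm.tp + cm.fn == 0 or cm.tp == 0:
        warnings.warn(
            "degenerate confusion matrix (no true positives); F1 set to 0",
            UserWarning,
            stacklevel=2,
        )
        return 0.0
    precision = cm.tp / (cm.tp + cm.fp)
    recall = cm.tp / (cm.tp + cm.fn)
    return 2 * precision * recall / (precision + recall)


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """P(random minor cell outscores a random major cell), ties half."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("AUC-ROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def _bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-value per column; constant columns give p = 1."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes raise precision warnings
        p = mannwhitneyu(a, b, alternative="two-sided", axis=0,
                         method="asymptotic").pvalue
    return np.nan_to_num(np.asarray(p, dtype=np.float64), nan=1.0)


def wilcoxon_markers(
    pm: ProcessedMatrix,
    cluster_labels: np.ndarray,
    fdr: float = 0.05,
    min_abs_fc: float = 1.5,
    pairwise: bool = True,
) -> pd.DataFrame:
    """Cluster marker genes by rank-sum test + BH + fold-change cutoff.

    For each cluster, every gene is tested two-sided against the rest
    (``pairwise=False``) or against each remaining cluster separately
    (``pairwise=True``, the default marker rule). Fold change is the ratio
    of group mean expression on the processed (log-scale) values. A gene is
    a marker iff in every comparison its BH-adjusted p <= ``fdr`` and its
    fold change is >= ``min_abs_fc`` in the up direction.

    Returns a table with one row per (cluster, gene) for the cluster-vs-rest
    statistics, with an ``is_marker`` column applying the pairwise rule.
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != pm.n_cells:
        raise ValueError("one label per cell required")
    values = pm.values
    clusters = [c for c in pd.unique(labels)]
    rows = []
    eps = 1e-12
    for cl in clusters:
        mask = labels == cl
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(
                f"cluster {cl!r} or its complement has fewer than 2 cells; skipped",
                UserWarning,
                stacklevel=2,
            )
            continue
        in_mean = values[mask].mean(axis=0)
        out_mean = values[~mask].mean(axis=0)
        praw = _rank_sum_columns(values[mask], values[~mask])
        padj = _bh(praw)
        fc = (in_mean + eps) / (out_mean + eps)
        direction = np.where(in_mean >= out_mean, "up", "down")

        if pairwise and len(clusters) > 2:
            qualifies = np.ones(pm.n_genes, dtype=bool)
            for other in clusters:
                if other == cl:
                    continue
                omask = labels == other
                if omask.sum() < 2:
                    continue
                p_pair = _bh(_rank_sum_columns(values[mask], values[omask]))
                o_mean = values[omask].mean(axis=0)
                fc_pair = (in_mean + eps) / (o_mean + eps)
                qualifies &= (p_pair <= fdr) & (fc_pair >= min_abs_fc)
        else:
            qualifies = (padj <= fdr) & (fc >= min_abs_fc)

        for g in range(pm.n_genes):
            rows.append(
                {
                    "cluster": cl,
                    "gene": pm.gene_ids[g],
                    "log2_fc": float(np.log2(fc[g])),
                    "fold_change": float(fc[g]),
                    "p_value": float(praw[g]),
                    "p_adjusted": float(padj[g]),
                    "direction": direction[g],
                    "is_marker": bool(qualifies[g]),
                }
            )
    return pd.DataFrame(rows)


def de_genes_two_group(
    pm: ProcessedMatrix,
    minor_flags: np.ndarray,
    fdr: float = 0.05,
    min_abs_log2_fc: float = np.log2(5),
) -> pd.DataFrame:
    """Two-group DE on processed values: rank-sum + BH + |log2 FC| cutoff.

    Fold change is the difference of group means on the log2 scale (i.e. a
    log2 ratio of geometric-mean-like expression). Returns per-gene
    statistics with an ``is_de`` call column.
    """
    minor = np.asarray(minor_flags, dtype=bool)
    values = pm.values
    praw = _rank_sum_columns(values[minor], values[~minor])
    padj = _bh(praw)
    log2_fc = values[minor].mean(axis=0) - values[~minor].mean(axis=0)
    is_de = (padj <= fdr) & (np.abs(log2_fc) >= min_abs_log2_fc)
    return pd.DataFrame(
        {
            "gene": pm.gene_ids,
            "log2_fc": log2_fc,
            "p_value": praw,
            "p_adjusted": padj,
            "is_de": is_de,
        }
    )
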