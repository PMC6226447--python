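"""Preprocessing chain for UMI/read count matrices.

The chain runs in a fixed order: cell QC by detected-gene count, gene
filtering by prevalence, median library-size normalization, dispersion-based
variable-gene selection, and a log2(x + 1) transform. The dispersion
statistic is computed on normalized but *unlogged* values; the log transform
is applied last, only over the selected genes.

Variable-gene selection ranks genes by a standardized dispersion: genes are
grouped into equal-occupancy bins by mean expression, and each gene's
dispersion (variance / mean) is centred and scaled by its bin's median and
median absolute deviation. This compensates for the mean–dispersion
relationship of count data so that selection favours genes more variable
than their expression peers, not merely highly expressed ones.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp

from .matrix import ProcessedMatrix, RawCountMatrix


class EmptyResultError(ValueError):
    """A filtering step removed every cell or every gene."""


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``min_detected_genes_per_cell`` is None to skip cell QC (droplet data
    from upstream pipelines is usually pre-filtered); typical values for
    plate/droplet data needing QC are 1800 or 1200 detected genes.
    """

    min_detected_genes_per_cell: int | None = None
    gene_min_count: float = 2
    gene_min_cells: int = 3
    n_top_genes: int = 1000
    n_dispersion_bins: int = 20
    pseudo_count: float = 1.0
    skip_normalization: bool = False

    def __post_init__(self) -> None:
        if self.min_detected_genes_per_cell is not None and (
            self.min_detected_genes_per_cell < 0
        ):
            raise ValueError("min_detected_genes_per_cell must be >= 0")
        if self.gene_min_count < 0:
            raise ValueError("gene_min_count must be >= 0")
        if self.gene_min_cells < 0:
            raise ValueError("gene_min_cells must be >= 0")
        if self.n_top_genes < 1:
            raise ValueError("n_top_genes must be >= 1")
        if self.n_dispersion_bins < 1:
            raise ValueError("n_dispersion_bins must be >= 1")


def _detected_per_cell(m: RawCountMatrix) -> np.ndarray:
    if sp.issparse(m.counts):
        return np.asarray((m.counts > 0).sum(axis=1)).ravel()
    return (m.counts > 0).sum(axis=1)


def filter_cells(m: RawCountMatrix, min_detected_genes: int) -> RawCountMatrix:
    """Keep cells with strictly more than ``min_detected_genes`` genes detected.

    A gene is detected in a cell if its count is > 0. The inequality is
    strict: a cell with exactly ``min_detected_genes`` detected genes is
    removed.
    """
    if min_detected_genes < 0:
        raise ValueError("min_detected_genes must be >= 0")
    detected = _detected_per_cell(m)
    keep = np.flatnonzero(detected > min_detected_genes)
    if keep.size == 0:
        raise EmptyResultError(
            f"cell QC removed all {m.n_cells} cells "
            f"(max detected genes: {detected.max() if len(detected) else 0}, "
            f"cutoff {min_detected_genes})"
        )
    return m.subset(cells=keep)


def filter_genes(
    m: RawCountMatrix, min_count: float = 2, min_cells: int = 3
) -> RawCountMatrix:
    """Keep genes whose count exceeds ``min_count`` in at least ``min_cells`` cells.

    Both comparisons follow the prevalence rule literally: count strictly
    greater than ``min_count``, in ``min_cells`` or more cells.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    if sp.issparse(m.counts):
        prevalence = np.asarray((m.counts > min_count).sum(axis=0)).ravel()
    else:
        prevalence = (m.counts > min_count).sum(axis=0)
    keep = np.flatnonzero(prevalence >= min_cells)
    if keep.size == 0:
        raise EmptyResultError(
            f"gene filter (count > {min_count} in >= {min_cells} cells) "
            f"removed all {m.n_genes} genes"
        )
    return m.subset(genes=keep)


def _cell_totals(m: RawCountMatrix) -> np.ndarray:
    if sp.issparse(m.counts):
        return np.asarray(m.counts.sum(axis=1)).ravel().astype(np.float64)
    return m.counts.sum(axis=1).astype(np.float64)


def median_normalize(m: RawCountMatrix) -> RawCountMatrix:
    """Scale each cell so its total equals the median of all cell totals."""
    totals = _cell_totals(m)
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(
            f"{bad} cell(s) have zero total count; filter cells before normalizing"
        )
    med = float(np.median(totals))
    factors = med / totals
    if sp.issparse(m.counts):
        scaled = sp.diags(factors) @ m.counts
    else:
        scaled = m.counts * factors[:, None]
    return RawCountMatrix(scaled, list(m.cell_ids), list(m.gene_ids))


class GeneSelection(NamedTuple):
    """Result of variable-gene selection: ranked indices + full statistic."""

    indices: np.ndarray  # selected gene column indices, best first
    dispersion: np.ndarray  # raw variance/mean per gene
    statistic: np.ndarray  # within-bin standardized dispersion per gene


def _gene_mean_var(m: RawCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    if sp.issparse(m.counts):
        mean = np.asarray(m.counts.mean(axis=0)).ravel()
        sq = np.asarray(m.counts.multiply(m.counts).mean(axis=0)).ravel()
        var = np.maximum(sq - mean**2, 0.0)
    else:
        mean = m.counts.mean(axis=0)
        var = m.counts.var(axis=0)
    return mean.astype(np.float64), var.astype(np.float64)


def select_variable_genes(
    m: RawCountMatrix, n_top: int = 1000, n_bins: int = 20
) -> GeneSelection:
    """Rank genes by dispersion standardized against similarly expressed genes.

    Genes are split into ``n_bins`` equal-occupancy bins by mean expression;
    within each bin the dispersion (variance/mean) is standardized by the
    bin median and MAD. Genes with zero mean get a statistic of -inf and are
    never selected. Ties rank by ascending original column index, so the
    result is deterministic.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    if n_bins > m.n_genes:
        raise ValueError(f"n_bins={n_bins} exceeds number of genes ({m.n_genes})")
    mean, var = _gene_mean_var(m)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    statistic = np.full(m.n_genes, -np.inf)
    valid = np.flatnonzero(mean > 0)
    if valid.size:
        # equal-occupancy bins: rank genes by mean, slice into n_bins chunks
        order = valid[np.argsort(mean[valid], kind="stable")]
        bins = np.array_split(order, min(n_bins, valid.size))
        for members in bins:
            d = dispersion[members]
            med = np.median(d)
            mad = np.median(np.abs(d - med))
            scale = mad if mad > 0 else 1e-12
            statistic[members] = (d - med) / scale
    # descending statistic, ties by ascending column index
    order = np.lexsort((np.arange(m.n_genes), -statistic))
    order = order[np.isfinite(statistic[order])]
    indices = order[: min(n_top, order.size)]
    return GeneSelection(indices=indices, dispersion=dispersion, statistic=statistic)


def anti_log(m: RawCountMatrix, base: float = 2.0,
             pseudo_count: float = 1.0) -> RawCountMatrix:
    """Undo an upstream log transform: x -> base**x - pseudo_count.

    For matrices distributed already log-transformed (some portals ship
    log2(x+1) values), apply this before the preprocessing chain so that
    normalization and dispersion selection see linear-scale values.
    """
    values = np.power(base, m.dense()) - pseudo_count
    values[np.abs(values) < 1e-12] = 0.0
    if values.min() < 0:
        raise ValueError("anti-log produced negative values; check pseudo_count")
    return RawCountMatrix(values, list(m.cell_ids), list(m.gene_ids))


def log_transform(m: RawCountMatrix, pseudo_count: float = 1.0) -> ProcessedMatrix:
    """Entrywise log2(x + pseudo_count) into a dense ProcessedMatrix."""
    dense = m.dense()
    if dense.size and dense.min() < 0:
        raise ValueError("log transform requires non-negative entries")
    values = np.log2(dense + pseudo_count)
    return ProcessedMatrix(
        values,
        list(m.cell_ids),
        list(m.gene_ids),
        provenance=[{"step": "log_transform", "params": {"pseudo_count": pseudo_count}}],
    )


def preprocess(m: RawCountMatrix, cfg: PreprocessConfig | None = None) -> ProcessedMatrix:
    """Full chain: cell QC -> gene filter -> median normalize -> select -> log.

    The variable-gene statistic is computed on the normalized, unlogged
    matrix; densification happens only over the selected gene subset, so
    sparse inputs stay sparse until the final transform.
    """
    cfg = cfg or PreprocessConfig()
    provenance: list[dict] = []

    if cfg.min_detected_genes_per_cell is not None:
        m = filter_cells(m, cfg.min_detected_genes_per_cell)
        provenance.append(
            {
                "step": "filter_cells",
                "params": {"min_detected_genes": cfg.min_detected_genes_per_cell},
            }
        )
    m = filter_genes(m, cfg.gene_min_count, cfg.gene_min_cells)
    provenance.append(
        {
            "step": "filter_genes",
            "params": {"min_count": cfg.gene_min_count, "min_cells": cfg.gene_min_cells},
        }
    )
    if not cfg.skip_normalization:
        m = median_normalize(m)
        provenance.append({"step": "median_normalize", "params": {}})
    sel = select_variable_genes(m, cfg.n_top_genes, cfg.n_dispersion_bins)
    m = m.subset(genes=np.sort(sel.indices))
    provenance.append(
        {
            "step": "select_variable_genes",
            "params": {"n_top": cfg.n_top_genes, "n_bins": cfg.n_dispersion_bins,
                       "n_selected": int(len(sel.indices))},
        }
    )
    pm = log_transform(m, cfg.pseudo_count)
    pm.provenance = provenance + pm.provenance
    return pm


def config_record(cfg: PreprocessConfig) -> dict:
    """JSON-serializable echo of a config (for run metadata sidecars)."""
    return asdict(cfg)
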