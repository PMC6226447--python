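"""Count-matrix containers shared across the package.

Two containers move through the pipeline: :class:`RawCountMatrix` holds
non-negative cells × genes counts (dense ndarray or scipy sparse), and
:class:`ProcessedMatrix` holds the dense, filtered, normalized, gene-selected,
log-transformed values that the sketching stage consumes, together with a
provenance trail sufficient to re-run the preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import scipy.sparse as sp


def _as_2d(counts: Any) -> Any:
    if sp.issparse(counts):
        return sp.csr_matrix(counts)
    arr = np.asarray(counts)
    if arr.ndim != 2:
        raise ValueError(f"counts must be 2-dimensional, got shape {arr.shape}")
    return arr


@dataclass
class RawCountMatrix:
    """Cells × genes non-negative counts with string identifiers.

    ``counts`` may be a dense :class:`numpy.ndarray` or a scipy CSR matrix;
    every operation in :mod:`firescore.preprocess` accepts both.
    """

    counts: Any
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = _as_2d(self.counts)
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix rows"
            )
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix columns"
            )
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("cell_ids must be unique")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("gene_ids must be unique")
        if self.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def min(self) -> float:
        if sp.issparse(self.counts):
            if self.counts.nnz == 0:
                return 0.0
            return min(0.0, float(self.counts.data.min()))
        if self.counts.size == 0:
            return 0.0
        return float(self.counts.min())

    def dense(self) -> np.ndarray:
        """Counts as a dense float64 array."""
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=np.float64)
        return np.asarray(self.counts, dtype=np.float64)

    def subset(self, cells: np.ndarray | None = None,
               genes: np.ndarray | None = None) -> "RawCountMatrix":
        """New matrix restricted to the given cell / gene index arrays."""
        counts = self.counts
        cell_ids = self.cell_ids
        gene_ids = self.gene_ids
        if cells is not None:
            cells = np.asarray(cells)
            counts = counts[cells, :]
            cell_ids = [cell_ids[i] for i in cells]
        if genes is not None:
            genes = np.asarray(genes)
            counts = counts[:, genes]
            gene_ids = [gene_ids[j] for j in genes]
        return RawCountMatrix(counts, cell_ids, gene_ids)


@dataclass
class ProcessedMatrix:
    """Dense preprocessed expression ready for sketching.

    ``provenance`` is an ordered list of ``{"step": name, "params": {...}}``
    records, one per preprocessing step in application order.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.size and self.values.min() < 0:
            raise ValueError("processed values must be non-negative")
        if len(self.cell_ids) != self.values.shape[0]:
            raise ValueError("cell_ids length mismatch")
        if len(self.gene_ids) != self.values.shape[1]:
            raise ValueError("gene_ids length mismatch")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]
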