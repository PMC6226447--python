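"""Randomized L1-preserving sketching and bucket-occupancy density estimates.

Each of L estimators picks M genes without replacement, a uniform threshold
per gene inside the observed [min, max] range of the expression matrix (by
default the global matrix range; optionally each gene's own range), and M
integer weights drawn uniformly from [1, 2^16). A cell's sketch is the
M-bit vector with bit j set iff its expression on gene j strictly exceeds
the threshold; the
sketch hashes to bucket (sum_j bit_j * w_j) mod H in exact integer
arithmetic. Cells that land in the same bucket are approximately close in
weighted L1 distance, so the fraction of all cells sharing cell i's bucket,

    p_il = |bucket containing i under estimator l| / N,

is an occupancy-based density estimate: rare cells sit in sparsely occupied
buckets and get small p_il across estimators.

Randomness discipline: estimator l draws from a generator keyed on
(root seed, l), so a given (seed, estimator index) pair always produces the
same estimator regardless of evaluation order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sympy import nextprime

from .matrix import ProcessedMatrix

WEIGHT_HIGH = 2**16  # weights drawn from [1, 2^16); exclusive upper bound

DEFAULT_L = 100
DEFAULT_M = 50
DEFAULT_H = 1_017_881  # prime; comfortably > 10x cells for typical datasets


@dataclass
class SketchParams:
    """Sketching hyperparameters.

    L estimators of M genes each, hashed into an H-slot table. H should be a
    prime exceeding 10x the number of cells; :func:`check_table_size` warns
    (and suggests the next suitable prime) when it does not, but never
    silently changes H.

    ``global_threshold_range`` controls where thresholds are drawn: from the
    global [min, max] of the whole expression matrix (default — sparse genes
    then often yield constant bits, which is what lets cells of an abundant
    population share buckets), or from each selected gene's own range.
    """

    L: int = DEFAULT_L
    M: int = DEFAULT_M
    H: int = DEFAULT_H
    seed: int = 0
    global_threshold_range: bool = True

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.H < 2:
            raise ValueError("H must be >= 2")


@dataclass
class Estimator:
    """One randomized hash function: gene subset, thresholds, integer weights."""

    gene_indices: np.ndarray  # M distinct ints in [0, n_genes)
    thresholds: np.ndarray  # M floats within each gene's observed range
    weights: np.ndarray  # M ints in [1, 2^16)

    def __post_init__(self) -> None:
        self.gene_indices = np.asarray(self.gene_indices, dtype=np.int64)
        self.thresholds = np.asarray(self.thresholds, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.int64)
        m = len(self.gene_indices)
        if len(self.thresholds) != m or len(self.weights) != m:
            raise ValueError("gene_indices, thresholds, weights must share length")
        if len(np.unique(self.gene_indices)) != m:
            raise ValueError("gene_indices must be distinct")
        if (self.weights < 1).any() or (self.weights >= WEIGHT_HIGH).any():
            raise ValueError(f"weights must lie in [1, {WEIGHT_HIGH})")


@dataclass
class BucketAssignment:
    """Per-cell bucket ids and bucket occupancy counts for one estimator."""

    bucket_of_cell: np.ndarray
    occupancy: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bucket_of_cell = np.asarray(self.bucket_of_cell, dtype=np.int64)
        if not self.occupancy:
            ids, counts = np.unique(self.bucket_of_cell, return_counts=True)
            self.occupancy = {int(b): int(c) for b, c in zip(ids, counts)}

    @property
    def n_cells(self) -> int:
        return len(self.bucket_of_cell)

    def counts_for_cells(self) -> np.ndarray:
        """Occupancy of each cell's own bucket, aligned to cell order."""
        _, inverse, counts = np.unique(
            self.bucket_of_cell, return_inverse=True, return_counts=True
        )
        return counts[inverse]


@dataclass
class DensityEstimates:
    """n_cells × L matrix of bucket-occupancy probabilities p_il."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=np.float64)
        if self.p.ndim != 2:
            raise ValueError("p must be n_cells x L")
        if self.p.size and ((self.p <= 0).any() or (self.p > 1).any()):
            raise ValueError("densities must lie in (0, 1]")


def check_table_size(H: int, n_cells: int) -> None:
    """Warn when the hash table is small relative to the number of cells."""
    if H <= 10 * n_cells:
        suggestion = int(nextprime(10 * n_cells))
        warnings.warn(
            f"hash table size H={H} is not greater than 10x the number of "
            f"cells ({n_cells}); collisions between dissimilar cells become "
            f"likely. Consider H={suggestion} (next prime above 10N).",
            UserWarning,
            stacklevel=2,
        )


def _rng_for(seed: int, estimator_index: int) -> np.random.Generator:
    return np.random.default_rng([seed, estimator_index])


def sample_estimator(
    gene_min: np.ndarray,
    gene_max: np.ndarray,
    params: SketchParams,
    estimator_index: int,
) -> Estimator:
    """Draw one estimator deterministically from (params.seed, estimator_index).

    ``gene_min`` / ``gene_max`` are the per-gene observed minima and maxima
    of the matrix being sketched. With ``global_threshold_range`` (the
    default) every threshold is drawn from the global [min, max] of the
    matrix; otherwise from the selected gene's own range.
    """
    gene_min = np.asarray(gene_min, dtype=np.float64)
    gene_max = np.asarray(gene_max, dtype=np.float64)
    n_genes = len(gene_min)
    if params.M > n_genes:
        raise ValueError(f"M={params.M} exceeds number of genes ({n_genes})")
    rng = _rng_for(params.seed, estimator_index)
    idx = rng.choice(n_genes, size=params.M, replace=False)
    if params.global_threshold_range:
        lo = np.full(params.M, gene_min.min())
        hi = np.full(params.M, gene_max.max())
    else:
        lo, hi = gene_min[idx], gene_max[idx]
    thresholds = rng.uniform(lo, hi)
    # uniform() needs lo < hi; constant genes get their constant as threshold
    degenerate = lo >= hi
    thresholds[degenerate] = lo[degenerate]
    weights = rng.integers(1, WEIGHT_HIGH, size=params.M, dtype=np.int64)
    return Estimator(idx, thresholds, weights)


def sample_estimators(values: np.ndarray, params: SketchParams) -> list[Estimator]:
    """All L estimators for the given expression matrix."""
    gene_min = values.min(axis=0)
    gene_max = values.max(axis=0)
    return [
        sample_estimator(gene_min, gene_max, params, l) for l in range(params.L)
    ]


def compute_sketch(cell_values: np.ndarray, e: Estimator) -> np.ndarray:
    """M-bit sketch of one cell: bit j = 1 iff value_j > threshold_j (strict)."""
    cell_values = np.asarray(cell_values, dtype=np.float64)
    if cell_values.shape[-1] != len(e.thresholds):
        raise ValueError(
            f"expected {len(e.thresholds)} values aligned to the estimator, "
            f"got {cell_values.shape[-1]}"
        )
    return (cell_values > e.thresholds).astype(np.int8)


def hash_sketch(bits: np.ndarray, e: Estimator, H: int) -> int:
    """Bucket id: integer dot product of bits and weights, mod H."""
    bits = np.asarray(bits, dtype=np.int64)
    if bits.shape[-1] != len(e.weights):
        raise ValueError("bit vector length does not match estimator weights")
    return int(bits @ e.weights % H)


def build_buckets(pm: ProcessedMatrix | np.ndarray, e: Estimator,
                  H: int) -> BucketAssignment:
    """Hash every cell of the matrix under one estimator (vectorized)."""
    values = pm.values if isinstance(pm, ProcessedMatrix) else np.asarray(pm)
    if values.shape[0] == 0:
        raise ValueError("cannot bucket an empty matrix")
    sub = values[:, e.gene_indices]
    bits = (sub > e.thresholds).astype(np.int64)
    buckets = (bits @ e.weights) % H
    return BucketAssignment(buckets)


def density_estimates(
    assignments: list[BucketAssignment], n_cells: int
) -> DensityEstimates:
    """Stack per-estimator occupancy fractions into the n_cells × L matrix."""
    for i, a in enumerate(assignments):
        if a.n_cells != n_cells:
            raise ValueError(
                f"estimator {i} covers {a.n_cells} cells, expected {n_cells}"
            )
    p = np.column_stack([a.counts_for_cells() / n_cells for a in assignments])
    return DensityEstimates(p)


def sketch_densities(
    pm: ProcessedMatrix | np.ndarray, params: SketchParams
) -> tuple[DensityEstimates, list[BucketAssignment], list[Estimator]]:
    """End-to-end first stage: estimators -> buckets -> densities."""
    values = pm.values if isinstance(pm, ProcessedMatrix) else np.asarray(pm)
    check_table_size(params.H, values.shape[0])
    estimators = sample_estimators(values, params)
    assignments = [build_buckets(values, e, params.H) for e in estimators]
    return density_estimates(assignments, values.shape[0]), assignments, estimators


def estimators_to_json(
    estimators: list[Estimator], params: SketchParams, path: str | Path
) -> None:
    """Serialize an estimator set so a scoring run is exactly reproducible."""
    payload = {
        "params": {
            "L": params.L,
            "M": params.M,
            "H": params.H,
            "seed": params.seed,
            "global_threshold_range": params.global_threshold_range,
        },
        "estimators": [
            {
                "gene_indices": e.gene_indices.tolist(),
                "thresholds": e.thresholds.tolist(),
                "weights": e.weights.tolist(),
            }
            for e in estimators
        ],
    }
    Path(path).write_text(json.dumps(payload))


def estimators_from_json(path: str | Path) -> tuple[list[Estimator], SketchParams]:
    payload = json.loads(Path(path).read_text())
    params = SketchParams(**payload["params"])
    estimators = [
        Estimator(
            np.array(e["gene_indices"]),
            np.array(e["thresholds"]),
            np.array(e["weights"]),
        )
        for e in payload["estimators"]
    ]
    return estimators, params
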