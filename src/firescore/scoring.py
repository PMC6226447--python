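"""Rareness scores from bucket-occupancy densities, plus rare-cell calls.

The per-cell score aggregates the L density estimates Fisher-style,

    score_i = -2 * sum_l ln(p_il),

so a cell sitting in sparsely occupied buckets under many estimators gets a
large score. With N cells the score lives in [0, 2 L ln N]: 0 when every
estimator puts the cell in a bucket with everyone else, the maximum when it
is a singleton everywhere. The binary rare/common call uses the Tukey fence:
a cell is rare iff its score >= q3 + 1.5 * IQR (inclusive), with quantiles
computed by linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .matrix import ProcessedMatrix
from .sketching import DensityEstimates, SketchParams, sketch_densities


@dataclass
class ScoreResult:
    """Scores, rare flags and the thresholding statistics of one run."""

    scores: np.ndarray
    rare_flags: np.ndarray
    threshold: float
    q3: float
    iqr: float
    params: SketchParams
    cell_ids: list[str] | None = None

    @property
    def n_rare(self) -> int:
        return int(self.rare_flags.sum())


def fire_scores(d: DensityEstimates | np.ndarray) -> np.ndarray:
    """Per-cell score -2 * sum_l ln(p_il) (natural log, unnormalized)."""
    p = d.p if isinstance(d, DensityEstimates) else np.asarray(d, dtype=np.float64)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("density estimates must lie in (0, 1]")
    return -2.0 * np.log(p).sum(axis=1)


def iqr_threshold(
    scores: np.ndarray, multiplier: float = 1.5, interpolation: str = "linear"
) -> tuple[float, np.ndarray]:
    """Tukey-fence dichotomization: rare iff score >= q3 + multiplier * IQR.

    Returns ``(threshold, rare_flags)``. Requires at least 4 scores; with
    fewer, the quartiles are too unstable to define a fence. When all
    scores are equal the IQR is 0 and every cell is flagged (the >= is
    inclusive); a warning is emitted because the call is then vacuous.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 4:
        raise ValueError(f"need >= 4 scores for quartile thresholding, got {scores.size}")
    q1, q3 = np.percentile(scores, [25, 75], method=interpolation)
    iqr = q3 - q1
    threshold = q3 + multiplier * iqr
    if iqr == 0 and np.allclose(scores, scores[0]):
        warnings.warn(
            "all scores equal: IQR is 0 and every cell meets the inclusive "
            "threshold; rare flags are uninformative",
            UserWarning,
            stacklevel=2,
        )
    return float(threshold), scores >= threshold


def select_top_fraction(scores: np.ndarray, fraction: float) -> np.ndarray:
    """Indices of the ceil(fraction * N) highest-scoring cells, best first.

    Ties break toward the lower cell index, so results are deterministic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score vector")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    k = int(np.ceil(fraction * scores.size))
    order = np.lexsort((np.arange(scores.size), -scores))
    return order[:k]


def score_matrix(
    pm: ProcessedMatrix | np.ndarray,
    params: SketchParams | None = None,
    iqr_multiplier: float = 1.5,
) -> ScoreResult:
    """Sketch, estimate densities, score and flag rare cells in one call."""
    params = params or SketchParams()
    densities, _, _ = sketch_densities(pm, params)
    scores = fire_scores(densities)
    threshold, flags = iqr_threshold(scores, iqr_multiplier)
    q1, q3 = np.percentile(scores, [25, 75])
    return ScoreResult(
        scores=scores,
        rare_flags=flags,
        threshold=threshold,
        q3=float(q3),
        iqr=float(q3 - q1),
        params=params,
        cell_ids=list(pm.cell_ids) if isinstance(pm, ProcessedMatrix) else None,
    )
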