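"""Simulation benchmark drivers: planted-rare recovery and DE sensitivity.

These functions wire the synthetic generator, the preprocessing chain and
the scorer into the two standard study designs:

* ``planted_rare_f1`` — plant a minor population at a controlled dilution
  into a major background, score, and report the F1 of the IQR-based rare
  call with respect to the minor population.
* ``de_sweep_aucs`` — from one simulated two-group dataset, identify a pool
  of strongly differential genes and a pool of clearly non-differential
  genes; then measure, as a function of k, how well the rareness score
  ranks minor cells when exactly k differential genes are present.
* ``hamming_l1_spearman`` — empirical check of the sketching premise: mean
  Hamming distance between sketches should track the range-normalized L1
  distance between expression profiles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy.stats import spearmanr

from .evaluation import auc_roc, confusion_from_flags, de_genes_two_group, f1_score
from .preprocess import PreprocessConfig, preprocess
from .scoring import score_matrix
from .simulate import (
    SimParams,
    UmiMixtureParams,
    de_gene_swap_experiment,
    plant_rare_mixture,
    simulate_two_groups,
    simulate_umi_mixture,
)
from .sketching import SketchParams, sample_estimators


def planted_rare_f1(
    rare_fraction: float = 0.025,
    seed: int = 0,
    n_major: int = 1950,
    n_top_genes: int = 1000,
    mixture_params: UmiMixtureParams | None = None,
    sketch_params: SketchParams | None = None,
) -> float:
    """F1 of the IQR rare call on a planted minor population.

    Simulates a droplet-like two-population pool (100 differential marker
    genes at median fold change 5 under the defaults), dilutes the minor
    group to ``rare_fraction`` of the mixture, preprocesses with defaults
    (gene filter, median normalization, top ``n_top_genes`` variable genes,
    log2), scores, and evaluates the IQR rare flags against the true minor
    labels.
    """
    rng = np.random.default_rng([seed, 2_001])
    if mixture_params is None:
        # pool sized so the major pool comfortably covers n_major cells and
        # the minor pool covers the dilution demand
        pool_cells = int(np.ceil(n_major * 1.12)) + 60
        mixture_params = UmiMixtureParams(
            n_cells=pool_cells, minor_prob=0.1, seed=int(rng.integers(2**31))
        )
    pool = simulate_umi_mixture(mixture_params)
    minor = pool.minor_flags()
    major_idx = np.flatnonzero(~minor)[:n_major]
    minor_idx = np.flatnonzero(minor)
    mixture = plant_rare_mixture(
        pool.counts.subset(cells=major_idx),
        pool.counts.subset(cells=minor_idx),
        rare_fraction,
        seed=int(rng.integers(2**31)),
    )
    pm = preprocess(mixture.counts, PreprocessConfig(n_top_genes=n_top_genes))
    params = sketch_params or SketchParams(seed=int(rng.integers(2**31)))
    result = score_matrix(pm, params)
    cm = confusion_from_flags(result.rare_flags, mixture.minor_flags())
    return f1_score(cm)


def de_sweep_pools(
    seed: int = 0,
    sim_params: SimParams | None = None,
    fdr: float = 0.05,
    min_abs_log2_fc: float = np.log2(5),
    nonde_p_floor: float = 0.05,
):
    """Simulate the sensitivity-study base data and identify gene pools.

    Returns ``(base, de_pool, nonde_pool)``. The differential pool holds
    genes detected at BH FDR <= ``fdr`` with |log2 fold change| >=
    ``min_abs_log2_fc`` on the log2-transformed filtered counts; the
    non-differential pool holds genes with raw p > ``nonde_p_floor``.
    """
    params = sim_params or SimParams(seed=seed)
    if sim_params is None:
        params = replace(params, seed=seed)
    base = simulate_two_groups(params)
    pm = preprocess(
        base.counts,
        PreprocessConfig(
            n_top_genes=base.counts.n_genes,
            n_dispersion_bins=1,
            skip_normalization=True,
        ),
    )
    # map processed gene columns back to original gene indices
    name_to_col = {g: j for j, g in enumerate(base.counts.gene_ids)}
    kept = np.array([name_to_col[g] for g in pm.gene_ids])
    table = de_genes_two_group(
        pm, base.minor_flags(), fdr=fdr, min_abs_log2_fc=min_abs_log2_fc
    )
    de_pool = kept[table["is_de"].to_numpy()]
    nonde_pool = kept[
        (table["p_value"].to_numpy() > nonde_p_floor) & ~table["is_de"].to_numpy()
    ]
    return base, de_pool, nonde_pool


def de_sweep_aucs(
    k: int,
    n_reps: int = 50,
    seed: int = 0,
    base=None,
    de_pool: np.ndarray | None = None,
    nonde_pool: np.ndarray | None = None,
    sketch_params: SketchParams | None = None,
) -> np.ndarray:
    """AUC-ROC values over ``n_reps`` swap repetitions at a fixed k.

    Pass ``base``/``de_pool``/``nonde_pool`` from :func:`de_sweep_pools` to
    reuse one simulated dataset across several k values (the standard sweep
    design); otherwise they are generated from ``seed``.
    """
    if base is None or de_pool is None or nonde_pool is None:
        base, de_pool, nonde_pool = de_sweep_pools(seed=seed)
    return de_gene_swap_experiment(
        base,
        de_pool,
        nonde_pool,
        k=k,
        n_reps=n_reps,
        seed=seed,
        sketch_params=sketch_params,
    )


def hamming_l1_spearman(
    n_cells: int = 120,
    n_genes: int = 500,
    n_pairs: int = 200,
    params: SketchParams | None = None,
    seed: int = 0,
    cell_scale_sigma: float = 0.3,
) -> float:
    """Spearman correlation between mean Hamming and normalized L1 distance.

    Draws a Gaussian expression fixture with log-normal per-cell scale
    factors (so pair distances actually spread instead of concentrating),
    sketches it with L estimators of M bits, and compares the mean Hamming
    distance across estimators with the per-gene-range-normalized L1
    distance on ``n_pairs`` random cell pairs.
    """
    params = params or SketchParams(seed=seed)
    rng = np.random.default_rng([seed, 77])
    values = rng.normal(loc=5.0, scale=2.0, size=(n_cells, n_genes))
    if cell_scale_sigma > 0:
        scale = rng.lognormal(0.0, cell_scale_sigma, n_cells)
        values = 5.0 + (values - 5.0) * scale[:, None]
    estimators = sample_estimators(values, params)
    # all sketches, stacked (L, n_cells, M)
    bits = np.stack(
        [(values[:, e.gene_indices] > e.thresholds) for e in estimators]
    )
    gene_range = values.max(axis=0) - values.min(axis=0)
    pairs = np.column_stack(
        [rng.integers(n_cells, size=n_pairs), rng.integers(n_cells, size=n_pairs)]
    )
    same = pairs[:, 0] == pairs[:, 1]
    pairs[same, 1] = (pairs[same, 1] + 1) % n_cells
    hamming = np.array(
        [
            (bits[:, i, :] != bits[:, j, :]).sum(axis=1).mean()
            for i, j in pairs
        ]
    )
    l1 = np.array(
        [np.abs((values[i] - values[j]) / gene_range).sum() for i, j in pairs]
    )
    rho = spearmanr(hamming, l1).statistic
    return float(rho)
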