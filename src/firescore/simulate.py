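"""Synthetic two-population count generators and benchmark designs.

Two generators cover the two benchmark settings:

* :func:`simulate_two_groups` emulates a splatter-style "groups" simulation
  at read-level depth: log-normal gene base means, a minor group carrying
  multiplicative log-normal DE factors with random direction, per-cell
  log-normal library-size factors, and negative-binomial counts whose
  dispersion follows the splatter convention (a common squared biological
  CV plus a Poisson-driven 1/sqrt(mu) term). It feeds the DE-gene
  sensitivity sweep, where only the ranking of rareness scores matters.

* :func:`simulate_umi_mixture` emulates sparse droplet (UMI) data with the
  gene-class structure real mixtures have: a small housekeeping backbone
  that anchors library size (tight, highly expressed, never selected as
  variable), a band of tightly expressed marker-class genes from which the
  differential genes are drawn, and an ultra-sparse bursty transcriptional
  bulk (mostly zeros per gene, occasional large values). This structure is
  what makes a major population co-bucket under L1-preserving sketches
  while a planted minor population does not, mirroring cell-line mixture
  benchmarks; it feeds the planted-rare dilution design.

Neither generator models dropout as a separate process (sparsity arises
from the count model itself), ambient RNA, or doublets.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import ceil, log

import numpy as np
import scipy.sparse as sp

from .evaluation import auc_roc
from .matrix import RawCountMatrix
from .preprocess import PreprocessConfig, preprocess
from .scoring import fire_scores
from .sketching import SketchParams, sketch_densities

MAJOR, MINOR = "major", "minor"


def _nb(rng: np.random.Generator, mu: np.ndarray,
        dispersion: np.ndarray | float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2."""
    dispersion = np.broadcast_to(np.asarray(dispersion, dtype=np.float64), mu.shape)
    r = 1.0 / dispersion
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _lib_factors(rng: np.random.Generator, n: int, cv: float) -> np.ndarray:
    """Log-normal library-size factors with mean 1 and the given CV."""
    if cv <= 0:
        return np.ones(n)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(-sigma**2 / 2, sigma, size=n)


def _de_factors(rng: np.random.Generator, n: int, loc: float,
                scale: float) -> np.ndarray:
    """Multiplicative fold changes exp(N(loc, scale)), direction random."""
    f = np.exp(rng.normal(loc, scale, size=n))
    down = rng.random(n) < 0.5
    f[down] = 1.0 / f[down]
    return f


@dataclass
class SimParams:
    """Parameters of the splatter-style two-group simulation.

    Defaults follow the splatter groups design: 500 cells, 5000 genes, a 5%
    minor group, and per-group differential expression — EACH group draws
    its own ``n_de_genes`` genes (40% of genes by default) and multiplies
    their means by factors exp(Normal(0.4, 0.8)) with random direction, so
    a gene differs between the groups when the two group factors differ.
    ``base_mean_log_mu``/``log_sigma`` give the
    log-normal distribution of per-gene base means; the defaults match the
    log-scale moments of splatter's gamma mean model at its default read
    depth (mean about 12 counts per gene, with a substantial sparse tail). ``nb_dispersion`` is the squared common biological CV
    (splatter's bcv.common^2); the realized dispersion of an entry with
    mean mu is (sqrt(nb_dispersion) + 1/sqrt(mu))^2, so shallow genes are
    noisy and deep genes approach the common BCV. ``libsize_cv`` is the CV
    of per-cell library-size factors.
    """

    n_cells: int = 500
    n_genes: int = 5000
    minor_prob: float = 0.05
    n_de_genes: int | None = None  # default: 40% of n_genes (de.prob = 0.4)
    de_fac_loc: float = 0.4
    de_fac_scale: float = 0.8
    base_mean_log_mu: float = 1.3
    base_mean_log_sigma: float = 1.55
    nb_dispersion: float = 0.01
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minor_prob < 1:
            raise ValueError("minor_prob must lie in (0, 1)")
        if self.n_de_genes is None:
            self.n_de_genes = int(round(0.4 * self.n_genes))
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes cannot exceed n_genes")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.libsize_cv < 0:
            raise ValueError("libsize_cv must be >= 0")
        if self.n_cells < 2 or self.n_genes < 1:
            raise ValueError("need at least 2 cells and 1 gene")


@dataclass
class SyntheticDataset:
    """Generated counts plus ground truth: labels, DE mask, fold changes."""

    counts: RawCountMatrix
    labels: np.ndarray  # per-cell, "major" or "minor"
    de_mask: np.ndarray  # per-gene bool, True where fold change != 1
    true_fold_changes: np.ndarray  # per-gene multiplicative factor (minor/major)
    params: dict | None = None
    gene_classes: np.ndarray | None = None  # per-gene class label, if structured

    def minor_flags(self) -> np.ndarray:
        return np.asarray(self.labels) == MINOR


def _group_folds(rng: np.random.Generator, p: SimParams) -> tuple[np.ndarray,
                                                                  np.ndarray]:
    """Per-group fold vectors (major, minor), each over its own DE draw."""
    folds = []
    for _ in range(2):
        de_idx = rng.choice(p.n_genes, size=p.n_de_genes, replace=False)
        fold = np.ones(p.n_genes)
        fold[de_idx] = _de_factors(rng, p.n_de_genes, p.de_fac_loc,
                                   p.de_fac_scale)
        folds.append(fold)
    return folds[0], folds[1]


def expected_means(p: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Theoretical per-gene count means for (major, minor) cells at lib = 1.

    Reconstructs the same base means and fold changes the generator draws
    for ``p.seed``, without sampling counts.
    """
    rng = np.random.default_rng(p.seed)
    base = rng.lognormal(p.base_mean_log_mu, p.base_mean_log_sigma, p.n_genes)
    rng.random(p.n_cells)  # label draw, consumed to stay stream-aligned
    fold_major, fold_minor = _group_folds(rng, p)
    return base * fold_major, base * fold_minor


def simulate_two_groups(p: SimParams) -> SyntheticDataset:
    """Draw one labeled two-group dataset; bit-identical for equal seeds."""
    rng = np.random.default_rng(p.seed)
    base = rng.lognormal(p.base_mean_log_mu, p.base_mean_log_sigma, p.n_genes)
    labels = np.where(rng.random(p.n_cells) < p.minor_prob, MINOR, MAJOR)
    # degenerate draws happen at small n; force at least one cell per group
    if (labels == MINOR).sum() == 0:
        labels[rng.integers(p.n_cells)] = MINOR
    elif (labels == MAJOR).sum() == 0:
        labels[rng.integers(p.n_cells)] = MAJOR

    fold_major, fold_minor = _group_folds(rng, p)
    rel_fold = fold_minor / fold_major
    de_mask = rel_fold != 1.0

    lib = _lib_factors(rng, p.n_cells, p.libsize_cv)
    mu = np.outer(lib, base)
    minor = labels == MINOR
    mu[~minor] = mu[~minor] * fold_major
    mu[minor] = mu[minor] * fold_minor
    bcv = np.sqrt(p.nb_dispersion) + 1.0 / np.sqrt(np.maximum(mu, 1e-12))
    counts = _nb(rng, mu, bcv**2)

    m = RawCountMatrix(
        counts,
        [f"cell{i}" for i in range(p.n_cells)],
        [f"gene{j}" for j in range(p.n_genes)],
    )
    return SyntheticDataset(m, labels, de_mask, rel_fold, params=asdict(p))


@dataclass
class UmiMixtureParams:
    """Parameters of the droplet-like (UMI) mixture simulation.

    Genes fall into three classes. ``hk_frac`` of genes are a housekeeping
    backbone: highly expressed (log-normal means around e^3.4 ~ 30 counts),
    low dispersion, carrying most of the library so that per-cell totals
    are stable under normalization. ``n_marker_genes`` form an expressed
    marker band (means around e^2.5 ~ 12 counts, tight dispersion, the way
    cell-identity markers behave within a homogeneous population); the
    ``n_de_genes`` differential genes are drawn from this band and get
    fold changes exp(N(de_fac_loc, de_fac_scale)) with random direction,
    so at the default loc = ln 5 the median |fold change| is 5. All other
    genes are bursty bulk: mostly zero in any one cell with occasional
    large values (dispersion rising as 1/mean^2 toward low means), the
    sparsity pattern that dominates real droplet matrices.
    """

    n_cells: int = 2000
    n_genes: int = 3000
    minor_prob: float = 0.025
    n_de_genes: int = 100
    de_fac_loc: float = log(5)
    de_fac_scale: float = 0.8
    hk_frac: float = 0.07
    hk_mean_log_mu: float = 3.4
    hk_mean_log_sigma: float = 0.4
    hk_dispersion: float = 0.05
    n_marker_genes: int = 150
    marker_mean_log_mu: float = 2.5
    marker_mean_log_sigma: float = 0.4
    marker_dispersion: float = 0.1
    bulk_mean_log_mu: float = -2.5
    bulk_mean_log_sigma: float = 1.3
    bulk_dispersion_base: float = 0.3
    bulk_dispersion_scale: float = 2.5
    libsize_cv: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.minor_prob < 1:
            raise ValueError("minor_prob must lie in (0, 1)")
        if self.n_de_genes > self.n_marker_genes:
            raise ValueError("n_de_genes cannot exceed the marker band size")
        n_hk = int(self.hk_frac * self.n_genes)
        if n_hk + self.n_marker_genes >= self.n_genes:
            raise ValueError("housekeeping + marker genes exceed n_genes")


def simulate_umi_mixture(p: UmiMixtureParams) -> SyntheticDataset:
    """Draw one sparse UMI-like two-population mixture with gene classes."""
    rng = np.random.default_rng(p.seed)
    n_hk = int(p.hk_frac * p.n_genes)
    n_bulk = p.n_genes - n_hk - p.n_marker_genes
    base = np.concatenate(
        [
            rng.lognormal(p.hk_mean_log_mu, p.hk_mean_log_sigma, n_hk),
            rng.lognormal(p.marker_mean_log_mu, p.marker_mean_log_sigma,
                          p.n_marker_genes),
            rng.lognormal(p.bulk_mean_log_mu, p.bulk_mean_log_sigma, n_bulk),
        ]
    )
    classes = np.array(
        ["housekeeping"] * n_hk + ["marker"] * p.n_marker_genes + ["bulk"] * n_bulk
    )
    perm = rng.permutation(p.n_genes)
    base, classes = base[perm], classes[perm]
    dispersion = np.where(
        classes == "housekeeping",
        p.hk_dispersion,
        np.where(
            classes == "marker",
            p.marker_dispersion,
            p.bulk_dispersion_base + p.bulk_dispersion_scale / base**2,
        ),
    )

    labels = np.where(rng.random(p.n_cells) < p.minor_prob, MINOR, MAJOR)
    if (labels == MINOR).sum() == 0:
        labels[rng.integers(p.n_cells)] = MINOR

    de_idx = rng.choice(np.flatnonzero(classes == "marker"), p.n_de_genes,
                        replace=False)
    fold = np.ones(p.n_genes)
    fold[de_idx] = _de_factors(rng, p.n_de_genes, p.de_fac_loc, p.de_fac_scale)

    lib = _lib_factors(rng, p.n_cells, p.libsize_cv)
    mu = np.outer(lib, base)
    minor = labels == MINOR
    mu[minor] = mu[minor] * fold
    counts = _nb(rng, mu, np.broadcast_to(dispersion, mu.shape))

    m = RawCountMatrix(
        counts,
        [f"cell{i}" for i in range(p.n_cells)],
        [f"gene{j}" for j in range(p.n_genes)],
    )
    return SyntheticDataset(
        m, labels, fold != 1.0, fold, params=asdict(p), gene_classes=classes
    )


def plant_rare_mixture(
    major: RawCountMatrix,
    minor: RawCountMatrix,
    rare_fraction: float,
    seed: int = 0,
) -> SyntheticDataset:
    """Mix all major cells with a subsample of minors at a target dilution.

    The number of minors is the smallest count that brings the minor share
    to at least ``rare_fraction`` of the mixture: ceil(f * n_major / (1 - f)).
    Subsampling is without replacement and the combined cell order is
    shuffled, both seed-deterministically.
    """
    if not 0 < rare_fraction < 0.5:
        raise ValueError("rare_fraction must lie in (0, 0.5)")
    if major.n_genes != minor.n_genes:
        raise ValueError("major and minor matrices must share the gene axis")
    n_major = major.n_cells
    n_minor = ceil(rare_fraction * n_major / (1.0 - rare_fraction))
    if n_minor > minor.n_cells:
        raise ValueError(
            f"need {n_minor} minor cells for a {rare_fraction:.3%} dilution "
            f"of {n_major} majors, only {minor.n_cells} available"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(minor.n_cells, size=n_minor, replace=False)
    minor_sub = minor.subset(cells=np.sort(pick))

    if sp.issparse(major.counts) or sp.issparse(minor_sub.counts):
        stacked = sp.vstack(
            [sp.csr_matrix(major.counts), sp.csr_matrix(minor_sub.counts)]
        ).tocsr()
    else:
        stacked = np.vstack([major.dense(), minor_sub.dense()])
    labels = np.array([MAJOR] * n_major + [MINOR] * n_minor)
    order = rng.permutation(n_major + n_minor)
    cell_ids = [f"mix{i}" for i in range(n_major + n_minor)]
    mixed = RawCountMatrix(stacked[order], cell_ids, list(major.gene_ids))
    return SyntheticDataset(
        mixed,
        labels[order],
        np.zeros(major.n_genes, dtype=bool),
        np.ones(major.n_genes),
        params={"rare_fraction": rare_fraction, "seed": seed,
                "n_major": n_major, "n_minor": n_minor},
    )


def de_gene_swap_experiment(
    base: SyntheticDataset,
    de_pool: np.ndarray,
    nonde_pool: np.ndarray,
    k: int,
    n_reps: int = 50,
    seed: int = 0,
    sketch_params: SketchParams | None = None,
    preprocess_cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """AUC-ROC of rareness scores when exactly k differential genes are present.

    Per repetition: start from the non-DE gene pool, replace k random
    members with k random DE-pool genes, run the standard preprocessing
    chain (median normalization, top-1000 variable genes, log2; the gene
    prevalence filter is waived since the pools are already curated), score,
    and measure AUC-ROC against the minor-group labels. Returns the n_reps
    AUC values.
    """
    de_pool = np.asarray(de_pool)
    nonde_pool = np.asarray(nonde_pool)
    if np.intersect1d(de_pool, nonde_pool).size:
        raise ValueError("DE and non-DE pools must be disjoint")
    if k > de_pool.size:
        raise ValueError(f"k={k} exceeds DE pool size {de_pool.size}")
    if k > nonde_pool.size:
        raise ValueError(f"k={k} exceeds non-DE pool size {nonde_pool.size}")
    minor = base.minor_flags()
    dense = base.counts.dense()
    cfg = preprocess_cfg or PreprocessConfig(
        gene_min_count=0, gene_min_cells=1, n_top_genes=1000,
    )
    aucs = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        genes = nonde_pool.copy()
        if k:
            out = rng.choice(nonde_pool.size, size=k, replace=False)
            genes[out] = rng.choice(de_pool, size=k, replace=False)
        sub = RawCountMatrix(
            dense[:, genes],
            list(base.counts.cell_ids),
            [base.counts.gene_ids[g] for g in genes],
        )
        pm = preprocess(sub, cfg)
        base_params = sketch_params or SketchParams()
        params = SketchParams(
            L=base_params.L,
            M=min(base_params.M, pm.n_genes),
            H=base_params.H,
            seed=int(np.random.default_rng([seed, rep, 1]).integers(2**31)),
            global_threshold_range=base_params.global_threshold_range,
        )
        densities, _, _ = sketch_densities(pm, params)
        scores = fire_scores(densities)
        aucs[rep] = auc_roc(scores, minor)
    return aucs
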