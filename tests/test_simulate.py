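import numpy as np
import pytest
from scipy import stats

from firescore.evaluation import auc_roc
from firescore.simulate import (
    SimParams,
    UmiMixtureParams,
    de_gene_swap_experiment,
    expected_means,
    plant_rare_mixture,
    simulate_two_groups,
    simulate_umi_mixture,
)


class TestSimulateTwoGroups:
    def test_same_seed_bit_identical(self):
        p = SimParams(n_cells=80, n_genes=200, seed=9)
        a, b = simulate_two_groups(p), simulate_two_groups(p)
        np.testing.assert_array_equal(a.counts.dense(), b.counts.dense())
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.true_fold_changes, b.true_fold_changes)

    def test_minor_count_within_binomial_bounds(self):
        p = SimParams(n_cells=10_000, n_genes=20, minor_prob=0.05, seed=1)
        ds = simulate_two_groups(p)
        n_minor = int(ds.minor_flags().sum())
        sigma = np.sqrt(10_000 * 0.05 * 0.95)
        assert abs(n_minor - 500) < 3 * sigma

    def test_no_de_genes_yields_uniform_pvalues(self):
        # with zero differential genes the groups are exchangeable, so
        # per-gene rank-sum p-values are approximately uniform
        p = SimParams(n_cells=300, n_genes=400, n_de_genes=0,
                      minor_prob=0.3, seed=3)
        ds = simulate_two_groups(p)
        assert not ds.de_mask.any()
        minor = ds.minor_flags()
        counts = ds.counts.dense()
        pvals = np.array(
            [
                stats.mannwhitneyu(counts[minor, g], counts[~minor, g],
                                   alternative="two-sided").pvalue
                for g in range(0, 400, 4)
            ]
        )
        # discreteness of counts makes p-values slightly non-uniform;
        # the KS statistic still stays small under the null
        ks = stats.kstest(pvals, "uniform").statistic
        assert ks < 0.12

    def test_count_means_track_theoretical_means(self):
        # per-gene sample means stay within 3 sigma of the NB expectation
        p = SimParams(n_cells=2000, n_genes=50, minor_prob=0.05,
                      libsize_cv=0.0, seed=4)
        ds = simulate_two_groups(p)
        mu_major, _ = expected_means(p)
        major = ~ds.minor_flags()
        counts = ds.counts.dense()[major]
        n = counts.shape[0]
        bcv = np.sqrt(p.nb_dispersion) + 1 / np.sqrt(mu_major)
        var = mu_major + (bcv**2) * mu_major**2
        z = (counts.mean(0) - mu_major) / np.sqrt(var / n)
        assert np.all(np.abs(z) < 4)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SimParams(minor_prob=0.0)
        with pytest.raises(ValueError):
            SimParams(n_genes=10, n_de_genes=11)
        with pytest.raises(ValueError):
            SimParams(nb_dispersion=0)


class TestUmiMixture:
    def test_seed_determinism_and_gene_classes(self):
        p = UmiMixtureParams(n_cells=100, n_genes=400, n_marker_genes=40,
                             n_de_genes=20, seed=2)
        a, b = simulate_umi_mixture(p), simulate_umi_mixture(p)
        np.testing.assert_array_equal(a.counts.dense(), b.counts.dense())
        assert set(a.gene_classes) == {"housekeeping", "marker", "bulk"}
        # DE genes live in the marker band
        assert np.all(a.gene_classes[a.de_mask] == "marker")
        assert a.de_mask.sum() == 20

    def test_housekeeping_dominates_library(self):
        ds = simulate_umi_mixture(UmiMixtureParams(n_cells=100, seed=6))
        counts = ds.counts.dense()
        hk = ds.gene_classes == "housekeeping"
        assert counts[:, hk].sum() > 0.5 * counts.sum()


class TestPlantRareMixture:
    def _pools(self, n_major=1000, n_minor=60, seed=0):
        ds = simulate_umi_mixture(
            UmiMixtureParams(n_cells=2 * (n_major + n_minor) + 100,
                             minor_prob=0.5, n_genes=300, n_marker_genes=40,
                             n_de_genes=20, seed=seed)
        )
        minor = ds.minor_flags()
        assert (~minor).sum() >= n_major and minor.sum() >= n_minor
        major_pool = ds.counts.subset(cells=np.flatnonzero(~minor)[:n_major])
        minor_pool = ds.counts.subset(cells=np.flatnonzero(minor)[:n_minor])
        return major_pool, minor_pool

    def test_dilution_arithmetic(self):
        major, minor = self._pools()
        mixed = plant_rare_mixture(major, minor, 0.025, seed=1)
        n_minor = int(mixed.minor_flags().sum())
        assert n_minor == 26  # ceil(0.025 * 1000 / 0.975)
        assert mixed.counts.n_cells == 1026
        frac = n_minor / mixed.counts.n_cells
        assert abs(frac - 0.025) * mixed.counts.n_cells <= 1

    def test_exact_availability_uses_all_minors(self):
        major, minor = self._pools(n_major=100, n_minor=3)
        mixed = plant_rare_mixture(major, minor, 3 / 103, seed=1)
        assert int(mixed.minor_flags().sum()) == 3

    def test_insufficient_minors_raise_with_requirement(self):
        major, minor = self._pools(n_major=1000, n_minor=10)
        with pytest.raises(ValueError, match="need 26"):
            plant_rare_mixture(major, minor, 0.025)

    def test_seed_determinism(self):
        major, minor = self._pools()
        a = plant_rare_mixture(major, minor, 0.03, seed=5)
        b = plant_rare_mixture(major, minor, 0.03, seed=5)
        np.testing.assert_array_equal(a.counts.dense(), b.counts.dense())
        np.testing.assert_array_equal(a.labels, b.labels)


@pytest.fixture(scope="module")
def base_and_pools():
    from firescore.benchmarks import de_sweep_pools

    return de_sweep_pools(
        seed=11,
        sim_params=SimParams(n_cells=300, n_genes=1500, seed=11),
    )


class TestDeGeneSwap:
    def test_identical_seed_identical_aucs(self, base_and_pools):
        base, de, nonde = base_and_pools
        a = de_gene_swap_experiment(base, de, nonde, k=5, n_reps=3, seed=2)
        b = de_gene_swap_experiment(base, de, nonde, k=5, n_reps=3, seed=2)
        np.testing.assert_array_equal(a, b)

    def test_no_signal_at_k_zero(self, base_and_pools):
        base, de, nonde = base_and_pools
        aucs = de_gene_swap_experiment(base, de, nonde, k=0, n_reps=8, seed=3)
        assert abs(aucs.mean() - 0.5) < 0.1

    def test_many_de_genes_beat_few(self, base_and_pools):
        base, de, nonde = base_and_pools
        k_hi = min(60, de.size)
        few = de_gene_swap_experiment(base, de, nonde, k=2, n_reps=8, seed=4)
        many = de_gene_swap_experiment(base, de, nonde, k=k_hi, n_reps=8,
                                       seed=4)
        assert many.mean() > few.mean()

    def test_pool_validation(self, base_and_pools):
        base, de, nonde = base_and_pools
        with pytest.raises(ValueError, match="disjoint"):
            de_gene_swap_experiment(base, de, np.concatenate([nonde, de[:1]]),
                                    k=1)
        with pytest.raises(ValueError, match="exceeds"):
            de_gene_swap_experiment(base, de, nonde, k=de.size + 1)


def test_scores_rank_minor_population(tiny_auc_data=None):
    """End-to-end: scoring simulated data ranks minors above majors."""
    from firescore.preprocess import PreprocessConfig, preprocess
    from firescore.scoring import score_matrix
    from firescore.sketching import SketchParams

    ds = simulate_umi_mixture(UmiMixtureParams(n_cells=800, seed=3))
    pm = preprocess(ds.counts, PreprocessConfig())
    res = score_matrix(pm, SketchParams(seed=21))
    assert auc_roc(res.scores, ds.minor_flags()) > 0.9
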