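import json

import numpy as np
import pytest

from firescore.matrix import RawCountMatrix
from firescore.preprocess import (
    EmptyResultError,
    PreprocessConfig,
    anti_log,
    filter_cells,
    filter_genes,
    log_transform,
    median_normalize,
    preprocess,
    select_variable_genes,
)


def _matrix(counts):
    counts = np.asarray(counts)
    return RawCountMatrix(
        counts,
        [f"c{i}" for i in range(counts.shape[0])],
        [f"g{j}" for j in range(counts.shape[1])],
    )


class TestFilterCells:
    def test_detected_gene_cutoff_is_strict(self):
        # one cell detects 2 genes, one detects 3
        m = _matrix([[1, 1, 0], [1, 1, 1]])
        kept = filter_cells(m, 2)
        assert kept.cell_ids == ["c1"]
        assert kept.gene_ids == m.gene_ids  # gene set unchanged
        # a cell with exactly the cutoff is removed
        with pytest.raises(EmptyResultError):
            filter_cells(_matrix([[1, 1, 0]]), 2)

    def test_zero_cutoff_keeps_any_expressing_cell(self):
        m = _matrix([[0, 0], [1, 0]])
        assert filter_cells(m, 0).cell_ids == ["c1"]

    def test_idempotent(self, random_counts):
        once = filter_cells(random_counts, 30)
        twice = filter_cells(once, 30)
        assert twice.cell_ids == once.cell_ids


class TestFilterGenes:
    @pytest.mark.parametrize(
        "column,kept",
        [
            ([3, 3, 3, 0], True),  # >2 in exactly 3 cells
            ([3, 3, 0, 0], False),  # only 2 cells
            ([2, 2, 2, 2], False),  # "exceeding 2" is strict
        ],
    )
    def test_prevalence_rule(self, column, kept):
        counts = np.column_stack([column, [9, 9, 9, 9]])
        out = filter_genes(_matrix(counts), 2, 3)
        assert ("g0" in out.gene_ids) is kept

    def test_all_genes_removed_raises(self):
        with pytest.raises(EmptyResultError):
            filter_genes(_matrix([[1, 1], [1, 1], [1, 1]]), 2, 3)

    def test_idempotent(self, random_counts):
        once = filter_genes(random_counts, 2, 3)
        twice = filter_genes(once, 2, 3)
        assert twice.gene_ids == once.gene_ids


class TestMedianNormalize:
    def test_totals_equal_median_after_scaling(self):
        m = _matrix([[10, 0], [10, 10], [10, 20]])  # totals 10, 20, 30
        out = median_normalize(m)
        np.testing.assert_allclose(out.dense().sum(axis=1), [20, 20, 20],
                                   rtol=1e-9)
        np.testing.assert_allclose(out.dense()[0], [20, 0])

    def test_single_cell_and_equal_totals_unchanged(self):
        one = _matrix([[2, 3]])
        np.testing.assert_array_equal(median_normalize(one).dense(), [[2, 3]])
        eq = _matrix([[1, 3], [2, 2], [3, 1]])
        np.testing.assert_allclose(median_normalize(eq).dense(), eq.dense())

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError, match="filter"):
            median_normalize(_matrix([[0, 0], [1, 1]]))


class TestSelectVariableGenes:
    def test_all_genes_returned_when_n_top_covers(self):
        m = _matrix(np.random.default_rng(0).poisson(4, (30, 5)))
        sel = select_variable_genes(m, n_top=5, n_bins=2)
        assert sorted(sel.indices.tolist()) == [0, 1, 2, 3, 4]

    def test_duplicated_column_ties_break_by_index(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(5, 20)
        counts = np.column_stack([col, rng.poisson(5, 20), col])
        sel = select_variable_genes(_matrix(counts), n_top=3, n_bins=1)
        assert sel.statistic[0] == sel.statistic[2]
        # the duplicate with the lower original index ranks first
        assert list(sel.indices).index(0) < list(sel.indices).index(2)

    def test_high_dispersion_gene_ranks_first(self):
        # brute-force oracle: one gene with 100x the variance of its
        # equal-mean peers must top the ranking
        rng = np.random.default_rng(2)
        quiet = rng.normal(10, 0.5, size=(200, 9)).clip(min=0)
        loud = rng.normal(10, 5.0, size=(200, 1)).clip(min=0)
        counts = np.column_stack([quiet[:, :4], loud, quiet[:, 4:]])
        sel = select_variable_genes(_matrix(counts), n_top=10, n_bins=1)
        mean = counts.mean(axis=0)
        disp = counts.var(axis=0) / mean
        assert sel.indices[0] == int(np.argmax(disp)) == 4

    def test_permutation_equivariance(self, random_counts):
        sel = select_variable_genes(random_counts, n_top=10, n_bins=4)
        rng = np.random.default_rng(3)
        perm = rng.permutation(random_counts.n_genes)
        permuted = random_counts.subset(genes=perm)
        sel_p = select_variable_genes(permuted, n_top=10, n_bins=4)
        # map permuted selection back to original column labels
        back = {random_counts.gene_ids[perm[i]] for i in sel_p.indices}
        assert back == {random_counts.gene_ids[i] for i in sel.indices}

    def test_too_many_bins_raises(self, tiny_counts):
        with pytest.raises(ValueError, match="n_bins"):
            select_variable_genes(tiny_counts, n_top=2, n_bins=10)


class TestLogTransform:
    def test_closed_form_values(self):
        m = _matrix([[0, 1, 3]])
        out = log_transform(m, 1)
        np.testing.assert_allclose(out.values, [[0, 1, 2]])

    def test_anti_log_inverts(self, random_counts):
        pm = log_transform(random_counts, 1)
        back = anti_log(
            RawCountMatrix(pm.values, pm.cell_ids, pm.gene_ids), 2, 1
        )
        np.testing.assert_allclose(back.dense(), random_counts.dense(),
                                   atol=1e-9)


class TestPreprocessChain:
    def test_identity_config_reduces_to_log(self):
        m = _matrix([[1, 3], [3, 1]])  # equal totals, no filtering effect
        cfg = PreprocessConfig(gene_min_count=0, gene_min_cells=1,
                               n_top_genes=2, n_dispersion_bins=1)
        pm = preprocess(m, cfg)
        np.testing.assert_allclose(pm.values, np.log2(m.dense() + 1))

    def test_default_config_selects_1000_genes(self):
        from firescore.simulate import SimParams, simulate_two_groups

        ds = simulate_two_groups(SimParams(n_cells=120, n_genes=2500, seed=7))
        pm = preprocess(ds.counts, PreprocessConfig())
        assert pm.n_genes == 1000
        steps = [p["step"] for p in pm.provenance]
        assert steps == ["filter_genes", "median_normalize",
                         "select_variable_genes", "log_transform"]

    def test_provenance_serializes_and_run_reproduces(self, random_counts):
        cfg = PreprocessConfig(gene_min_count=1, gene_min_cells=2,
                               n_top_genes=12, n_dispersion_bins=3)
        pm = preprocess(random_counts, cfg)
        json.dumps(pm.provenance)  # serializable
        pm2 = preprocess(random_counts, cfg)
        np.testing.assert_array_equal(pm.values, pm2.values)
        assert pm.gene_ids == pm2.gene_ids
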