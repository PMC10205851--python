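"""QC arithmetic, adaptive mito antimode, normalization, VST, scaling, PCA."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from stemtyper.genesets import GeneSet
from stemtyper.preprocess import (
    LAYER_LOGNORM,
    log_normalize,
    pca,
    regress_and_scale,
    score_gene_module,
    select_variable_genes_vst,
)
from stemtyper.qc import (
    adaptive_mito_threshold,
    compute_qc,
    filter_cells,
    filter_cells_profile,
)

from conftest import make_adata


class TestComputeQC:
    def test_arithmetic_with_mito_gene(self):
        a = make_adata(np.array([[3.0, 1.0]]), genes=["GENEA", "MT-ND1"])
        qc = compute_qc(a)
        assert qc.iloc[0].tolist() == [2, 4.0, 25.0]

    def test_all_zero_cell_degenerate(self):
        a = make_adata(np.array([[0.0, 0.0], [1.0, 0.0]]), genes=["GENEA", "MT-ND1"])
        qc = compute_qc(a)
        assert qc.iloc[0].tolist() == [0, 0.0, 0.0]

    def test_no_mito_genes_warns_and_zeros(self, caplog):
        a = make_adata(np.ones((3, 2)), genes=["A", "B"])
        qc = compute_qc(a)
        assert (qc["pct_mito"] == 0).all()

    def test_mean_pct_mito_matches_generator_mixture(self, default_sim):
        adata, truth = default_sim
        qc = compute_qc(adata)
        assert abs(qc["pct_mito"].mean() - truth.params["expected_pct_mito"]) < 1.0


class TestAdaptiveMitoThreshold:
    def test_antimode_of_known_mixture(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(5, 1, 1800), rng.normal(20, 2, 200)])
        thr = adaptive_mito_threshold(x)
        assert 8.0 <= thr <= 17.0

    def test_unimodal_falls_back_to_95th_percentile(self):
        rng = np.random.default_rng(0)
        x = rng.normal(5, 1, 2000)
        thr = adaptive_mito_threshold(x)
        assert abs(thr - 6.645) < 0.3

    def test_two_spikes_threshold_between(self):
        x = np.concatenate([np.full(500, 4.0), np.full(500, 12.0)])
        thr = adaptive_mito_threshold(x)
        assert 4.0 < thr < 12.0

    def test_too_few_cells_instructs_fixed_mode(self):
        with pytest.raises(ValueError, match="fixed"):
            adaptive_mito_threshold(np.ones(50) * 5)


class TestFilterCells:
    def _toy(self):
        return pd.DataFrame(
            {"n_features": [2000, 1000, 2000], "n_counts": [30000, 30000, 70000], "pct_mito": [5.0, 5.0, 5.0]},
            index=["c1", "c2", "c3"],
        )

    def test_printed_three_cell_toy_retains_one(self):
        assert filter_cells(self._toy(), 1600, 65000, 16.0) == ["c1"]

    def test_no_op_thresholds_retain_all(self):
        qc = self._toy()
        assert filter_cells(qc, 1, 10**12, 100.0) == list(qc.index)

    def test_result_invariant_to_cell_order(self):
        qc = self._toy()
        shuffled = qc.sample(frac=1.0, random_state=1)
        assert set(filter_cells(qc, 1600, 65000, 16.0)) == set(filter_cells(shuffled, 1600, 65000, 16.0))

    def test_zero_survivors_reports_attrition(self):
        with pytest.raises(ValueError, match="fail n_features"):
            filter_cells(self._toy(), 10**6, 65000, 16.0)

    def test_published_data_profile(self):
        qc = pd.DataFrame(
            {"n_features": [5000, 9000, 5000], "n_counts": [20000, 20000, 500], "pct_mito": [5.0, 5.0, 5.0]},
            index=["a", "b", "c"],
        )
        assert filter_cells_profile(qc, "wu-published") == ["a"]

    def test_adaptive_filter_removes_dead_keeps_live(self, pipeline_result):
        res, truth = pipeline_result
        kept = set(res["adata"].obs_names)
        dead = truth.cells["is_dead"]
        removed_dead = sum(bc not in kept for bc in truth.cells.index[dead])
        removed_live = sum(
            bc not in kept for bc in truth.cells.index[~dead & ~truth.cells["is_doublet"]]
        )
        assert removed_dead / dead.sum() >= 0.90
        assert removed_live / (~dead).sum() <= 0.02


class TestLogNormalize:
    def test_formula_values(self):
        counts = np.zeros((1, 3))
        counts[0] = [5, 9995, 0]
        a = make_adata(counts)
        log_normalize(a)
        v = a.layers[LAYER_LOGNORM].toarray()[0]
        assert v[0] == pytest.approx(np.log(6.0), abs=1e-12)
        assert v[2] == 0.0

    def test_equal_counts_split_cell(self):
        a = make_adata(np.array([[1.0, 1.0]]))
        log_normalize(a)
        v = a.layers[LAYER_LOGNORM].toarray()[0]
        assert v[0] == pytest.approx(np.log(1 + 5000), abs=1e-12)
        assert v[0] == v[1]

    def test_zero_total_cell_rejected(self):
        a = make_adata(np.array([[0.0, 0.0], [1.0, 1.0]]))
        with pytest.raises(ValueError, match="zero total"):
            log_normalize(a)

    def test_monotone_within_cell(self):
        rng = np.random.default_rng(0)
        a = make_adata(rng.poisson(3.0, (20, 30)) + 1.0)
        log_normalize(a)
        X = np.asarray(a.X.todense())
        L = a.layers[LAYER_LOGNORM].toarray()
        for i in range(20):
            order = np.argsort(X[i])
            assert (np.diff(L[i][order]) >= -1e-12).all()


class TestVST:
    def test_planted_high_dispersion_recovered(self):
        rng = np.random.default_rng(0)
        n_cells, n_genes = 400, 500
        means = rng.gamma(2, 0.5, n_genes)
        X = rng.negative_binomial(50.0, 50.0 / (50.0 + means), (n_cells, n_genes)).astype(float)
        hi = rng.choice(n_genes, 20, replace=False)
        for j in hi:
            X[:, j] = rng.negative_binomial(0.2, 0.2 / (0.2 + means[j]), n_cells)
        a = make_adata(X)
        top = select_variable_genes_vst(a, 50)
        hi_names = {f"G{j}" for j in hi}
        assert len(hi_names & set(top.genes)) >= 18

    def test_identical_genes_tie_break_by_order(self):
        X = np.tile(np.arange(10.0)[:, None], (1, 6))
        a = make_adata(X)
        top = select_variable_genes_vst(a, 3)
        assert list(top.genes) == ["G0", "G1", "G2"]

    def test_n_exceeding_gene_count_returns_all(self):
        rng = np.random.default_rng(0)
        a = make_adata(rng.poisson(2.0, (50, 10)) + 1.0)
        top = select_variable_genes_vst(a, 50)
        assert len(top) == 10


class TestModuleScore:
    def test_null_module_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, (300, 500)).astype(float)
        a = make_adata(X, lognorm=X)
        score = score_gene_module(a, GeneSet("m", tuple(f"G{j}" for j in range(200, 210))), seed=0)
        assert abs(score.mean()) < 0.1

    def test_shifted_module_scores_near_shift(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, (500, 1000)).astype(float)
        X[:, :10] += 1.0
        a = make_adata(X, lognorm=X)
        score = score_gene_module(a, GeneSet("m", tuple(f"G{j}" for j in range(10))), n_bins=2, seed=0)
        assert score.mean() == pytest.approx(1.0, abs=0.1)

    def test_same_seed_same_controls(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(2.0, (100, 300)).astype(float)
        a = make_adata(X, lognorm=X)
        gs = GeneSet("m", ("G5", "G6", "G7"))
        assert np.array_equal(score_gene_module(a, gs, seed=3), score_gene_module(a, gs, seed=3))

    def test_missing_module_errors(self):
        a = make_adata(np.ones((5, 4)), lognorm=np.ones((5, 4)))
        with pytest.raises(ValueError, match="none of the module genes"):
            score_gene_module(a, GeneSet("m", ("ABSENT1",)), seed=0)


class TestRegressAndScale:
    def test_gene_linear_in_covariate_scales_to_zero(self):
        rng = np.random.default_rng(0)
        mito = rng.normal(5, 1, 200)
        Y = np.column_stack([2 * mito + 3, rng.normal(0, 1, 200)])
        a = make_adata(np.maximum(Y, 0), lognorm=Y)
        cov = pd.DataFrame({"pct_mito": mito}, index=a.obs_names)
        scaled = regress_and_scale(a, None, cov)
        assert np.abs(scaled.values[:, 0]).max() < 1e-8

    def test_no_covariates_reduces_to_zscore(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(0, 2, (100, 3))
        a = make_adata(np.maximum(Y, 0), lognorm=Y)
        scaled = regress_and_scale(a, None, None)
        expect = (Y - Y.mean(axis=0)) / Y.std(axis=0, ddof=1)
        assert np.allclose(scaled.values, expect, atol=1e-10)

    def test_rows_standardized_before_clip(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(1, 3, (150, 8))
        a = make_adata(np.maximum(Y, 0), lognorm=Y)
        cov = pd.DataFrame({"n_counts": rng.normal(0, 1, 150)}, index=a.obs_names)
        scaled = regress_and_scale(a, None, cov)
        assert np.abs(scaled.values.mean(axis=0)).max() < 1e-8
        assert np.allclose(scaled.values.var(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_residual_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        nc = rng.normal(0, 1, 300)
        Y = np.outer(nc, np.full(5, 2.0)) + rng.normal(0, 1, (300, 5))
        a = make_adata(np.maximum(Y, 0), lognorm=Y)
        scaled = regress_and_scale(a, None, pd.DataFrame({"n_counts": nc}, index=a.obs_names))
        for j in range(5):
            assert abs(np.corrcoef(scaled.values[:, j], nc)[0, 1]) < 0.05


class TestPCA:
    def test_rank_one_matrix_pc1_dominates(self):
        rng = np.random.default_rng(0)
        base = np.outer(rng.normal(0, 1, 100), rng.normal(0, 1, 20))
        from stemtyper.preprocess import ScaledMatrix

        sm = ScaledMatrix(tuple(f"G{j}" for j in range(20)), base + rng.normal(0, 1e-6, base.shape), (), 10.0)
        emb, evr = pca(sm, 5)
        assert evr[0] > 0.99

    def test_sign_convention_reproducible(self, pipeline_result):
        res, _ = pipeline_result
        emb2, _ = pca(res["scaled"], res["embedding"].shape[1])
        assert np.array_equal(res["embedding"], emb2)

    def test_pc1_separates_lines(self):
        from sklearn.metrics import roc_auc_score

        from stemtyper.pipeline import run_pipeline, synthetic_config
        from stemtyper.simulate import simulate_counts

        adata, truth = simulate_counts(n_lines=2, subclusters_per_line=1, cells_per_subcluster=80, seed=0)
        res = run_pipeline(adata, synthetic_config(0))
        lines = truth.cells.loc[res["adata"].obs_names, "line_id"] == "line0"
        auc = roc_auc_score(lines, res["embedding"][:, 0])
        assert max(auc, 1 - auc) > 0.95
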