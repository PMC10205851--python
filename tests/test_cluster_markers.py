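"""Clustering, Wilcoxon marker tables, gene-vector filter, cluster trees."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from stemtyper.cluster import build_cluster_tree, cluster_cells, nodal_split_markers
from stemtyper.markers import filter_gene_vector, wilcoxon_markers

from conftest import make_adata


class TestClusterCells:
    def test_two_blobs_exact_recovery(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(8, 1, (100, 5))])
        labels = cluster_cells(emb, k=15, resolution=0.8, seed=0)
        from sklearn.metrics import adjusted_rand_score

        assert len(set(labels)) == 2
        assert adjusted_rand_score([0] * 100 + [1] * 100, labels) == 1.0

    def test_cluster_count_nondecreasing_in_resolution(self):
        rng = np.random.default_rng(0)
        emb = np.vstack([rng.normal(0, 1, (100, 5)), rng.normal(8, 1, (100, 5))])
        counts = [len(set(cluster_cells(emb, k=15, resolution=r, seed=0))) for r in (0.2, 0.8, 3.0)]
        assert counts == sorted(counts)

    def test_single_blob_one_cluster(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(0, 1, (150, 5))
        assert len(set(cluster_cells(emb, k=15, resolution=0.2, seed=0))) == 1

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            cluster_cells(np.zeros((10, 3)), k=10)

    def test_planted_lines_recovered(self, pipeline_result):
        from sklearn.metrics import adjusted_rand_score

        res, truth = pipeline_result
        lines = truth.cells.loc[res["adata"].obs_names, "line_id"]
        assert adjusted_rand_score(lines, res["labels"]) >= 0.9


def brute_force_ranksum_p(x, y):
    """Independent exact two-sided rank-sum p by full enumeration."""
    vals = np.concatenate([x, y])
    n1, n = len(x), len(vals)
    r = rankdata(vals)
    mu = n1 * (n + 1) / 2.0
    obs = abs(r[:n1].sum() - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        total += 1
        if abs(r[list(idx)].sum() - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


class TestWilcoxonMarkers:
    def _two_group_adata(self, Xin, Xout):
        X = np.vstack([Xin, Xout])
        a = make_adata(X, lognorm=X)
        labels = np.array(["g"] * len(Xin) + ["r"] * len(Xout))
        return a, labels

    def test_exclusive_gene_pct_definition(self):
        Xin = np.column_stack([np.ones(10), np.zeros(10)])
        Xout = np.zeros((20, 2))
        a, labels = self._two_group_adata(Xin, Xout)
        t = wilcoxon_markers(a, labels, "g").set_index("gene")
        assert t.loc["G0", "pct.1"] == 1.0
        assert t.loc["G0", "pct.2"] == 0.0
        assert t.loc["G0", "difference"] == 1.0

    def test_identical_groups_null(self):
        block = np.tile(np.arange(6.0)[:, None], (1, 4))
        a, labels = self._two_group_adata(block, block)
        t = wilcoxon_markers(a, labels, "g")
        assert (t["p_val"] > 0.9).all()
        assert (t["avg_log2FC"] == 0).all()

    def test_exact_p_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(4):
            Xin = np.round(rng.gamma(1, 1, (6, 3)), 1)
            Xout = np.round(rng.gamma(1, 2, (8, 3)), 1)
            a, labels = self._two_group_adata(Xin, Xout)
            t = wilcoxon_markers(a, labels, "g").set_index("gene")
            for j in range(3):
                expect = brute_force_ranksum_p(Xin[:, j], Xout[:, j])
                assert abs(t.loc[f"G{j}", "p_val"] - expect) < 1e-10

    def test_bonferroni_and_invariants(self):
        rng = np.random.default_rng(0)
        Xin, Xout = rng.gamma(1, 1, (15, 20)), rng.gamma(1, 1, (25, 20))
        a, labels = self._two_group_adata(Xin, Xout)
        t = wilcoxon_markers(a, labels, "g")
        assert (t["p_val_adj"] >= t["p_val"]).all()
        assert t["pct.1"].between(0, 1).all() and t["pct.2"].between(0, 1).all()
        assert t["difference"].between(-1, 1).all()

    def test_planted_markers_recovered(self, pipeline_result):
        res, truth = pipeline_result
        adata = res["adata"]
        lab = pd.Series(res["labels"], index=adata.obs_names)
        lines = truth.cells.loc[adata.obs_names, "line_id"]
        cl = lab[lines == "line0"].mode()[0]
        t = wilcoxon_markers(adata, res["labels"], group=cl)
        planted = {g for g in adata.var_names if g.startswith("LINE0M")}
        top30 = set(t.nlargest(30, "avg_log2FC")["gene"])
        assert len(planted & top30) >= 18
        sig = t[t["gene"].isin(planted)]
        assert (sig["p_val_adj"] < 0.05).all()

    def test_empty_group_rejected(self):
        a, labels = self._two_group_adata(np.ones((5, 2)), np.ones((5, 2)))
        with pytest.raises(ValueError, match="empty group"):
            wilcoxon_markers(a, labels, "missing")


class TestFilterGeneVector:
    def _table(self, rows):
        return pd.DataFrame(
            [
                {
                    "gene": f"G{i}",
                    "p_val": 0.01,
                    "p_val_adj": 0.02,
                    "avg_log2FC": fc,
                    "pct.1": 0.9,
                    "pct.2": 0.9 - d,
                    "difference": d,
                    "cluster": "0",
                }
                for i, (fc, d) in enumerate(rows)
            ]
        )

    def test_boundary_is_strict(self):
        t = self._table([(0.8, 0.6), (1.2, 0.51)])
        kept = filter_gene_vector(t)
        assert kept["gene"].tolist() == ["G1"]

    def test_printed_six_record_toy(self):
        t = self._table([(1.0, 0.6), (0.9, 0.4), (0.7, 0.9), (2.0, 0.55), (0.81, 0.501), (-1.5, 0.8)])
        kept = filter_gene_vector(t)
        assert len(kept) == 3
        assert kept["gene"].tolist() == ["G0", "G3", "G4"]

    def test_subset_and_idempotent(self):
        rng = np.random.default_rng(0)
        t = self._table([(fc, d) for fc, d in zip(rng.normal(0.8, 0.5, 30), rng.uniform(0, 1, 30))])
        once = filter_gene_vector(t)
        assert set(once["gene"]) <= set(t["gene"])
        pd.testing.assert_frame_equal(filter_gene_vector(once), once)


class TestClusterTree:
    def test_nearest_pair_merges_first(self):
        emb = np.array([[0.0], [1.0], [10.0]] * 5)
        labels = np.array(["A", "B", "C"] * 5)
        tree = build_cluster_tree(emb, labels)
        first = min(tree.internal_nodes(), key=lambda nd: nd.height)
        assert set(first.members) == {"A", "B"}

    def test_identical_centroids_zero_heights(self):
        emb = np.zeros((9, 2))
        labels = np.array(["A", "B", "C"] * 3)
        tree = build_cluster_tree(emb, labels)
        assert all(nd.height == 0 for nd in tree.internal_nodes())

    def test_leaves_exactly_once_and_newick(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(0, 1, (40, 3))
        labels = np.repeat(["A", "B", "C", "D"], 10)
        tree = build_cluster_tree(emb, labels)
        assert sorted(tree.leaves) == ["A", "B", "C", "D"]
        nwk = tree.to_newick()
        assert nwk.endswith(";") and all(c in nwk for c in "ABCD")

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            build_cluster_tree(np.zeros((5, 2)), np.array(["A"] * 5))

    def test_subclusters_merge_within_line_first(self):
        from stemtyper.pipeline import run_pipeline, synthetic_config
        from stemtyper.simulate import simulate_counts

        adata, truth = simulate_counts(n_lines=2, subclusters_per_line=2, cells_per_subcluster=60, seed=0, sub_effect=6.0)
        res = run_pipeline(adata, synthetic_config(0))
        kept = res["adata"].obs_names
        key = (
            truth.cells.loc[kept, "line_id"].astype(str) + "/" + truth.cells.loc[kept, "subcluster_id"].astype(str)
        ).to_numpy()
        tree = build_cluster_tree(res["embedding"], key)
        # the first two merges should each join subclusters of one line
        nodes = sorted(tree.internal_nodes(), key=lambda nd: nd.height)
        for nd in nodes[:2]:
            lines = {m.split("/")[0] for m in nd.members}
            assert len(lines) == 1


class TestNodalSplitMarkers:
    def test_binary_tree_has_n_minus_one_marker_sets(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, (60, 40)).astype(float)
        a = make_adata(X, lognorm=np.log1p(X))
        labels = np.repeat(["A", "B", "C", "D"], 15)
        emb = np.column_stack([np.repeat([0.0, 1.0, 10.0, 11.0], 15), np.zeros(60)]) + rng.normal(0, 0.1, (60, 2))
        tree = build_cluster_tree(emb, labels)
        tree = nodal_split_markers(tree, a, labels)
        nodes = tree.internal_nodes()
        assert len(nodes) == 3
        assert all(nd.left_markers is not None and nd.right_markers is not None for nd in nodes)

    def test_identical_clusters_empty_vectors(self):
        rng = np.random.default_rng(0)
        X = rng.poisson(2.0, (40, 30)).astype(float)
        a = make_adata(X, lognorm=np.log1p(X))
        labels = np.array(["A", "B"] * 20)
        emb = rng.normal(0, 1, (40, 2))
        tree = build_cluster_tree(emb, labels)
        tree = nodal_split_markers(tree, a, labels)
        for nd in tree.internal_nodes():
            assert len(nd.left_markers) == 0 and len(nd.right_markers) == 0

    def test_root_split_recovers_planted_programs(self, pipeline_result):
        res, truth = pipeline_result
        adata = res["adata"]
        tree = build_cluster_tree(res["embedding"], res["labels"])
        tree = nodal_split_markers(tree, adata, res["labels"])
        root = tree.root
        vector = set(pd.concat([root.left_markers, root.right_markers])["gene"])
        # the root split separates one line from the others; its planted
        # program should dominate the nodal vector
        lab = pd.Series(res["labels"], index=adata.obs_names)
        lines = truth.cells.loc[adata.obs_names, "line_id"]
        best_overlap = 0.0
        for l in lines.unique():
            planted = {g for g in adata.var_names if g.startswith(f"LINE{l[-1]}M")}
            best_overlap = max(best_overlap, len(planted & vector) / len(planted))
        assert best_overlap >= 0.8

    def test_cumulative_vector_concatenates_ancestral_nodes(self, pipeline_result):
        res, _ = pipeline_result
        tree = build_cluster_tree(res["embedding"], res["labels"])
        tree = nodal_split_markers(tree, res["adata"], res["labels"])
        for leaf in tree.leaves:
            vec = tree.cumulative_gene_vector(leaf)
            ancestral = pd.concat(
                [
                    nd.left_markers if leaf in nd.left.members else nd.right_markers
                    for nd in tree.internal_nodes()
                    if leaf in nd.members
                ]
            )
            assert set(vec["gene"]) == set(ancestral["gene"])
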