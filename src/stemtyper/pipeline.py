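"""End-to-end per-sample pipeline: QC -> normalize -> scale -> PCA -> cluster.

Thin orchestration over the stage functions, driven by a RunConfig.
Used by the CLI and by determinism checks; each stage logs one
structured line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._log import logger
from .cluster import build_cluster_tree, cluster_cells, nodal_split_markers
from .config import RunConfig
from .genesets import bundled_gene_set
from .preprocess import log_normalize, pca, regress_and_scale, score_gene_module, select_variable_genes_vst
from .qc import adaptive_mito_threshold, compute_qc, filter_cells


def synthetic_config(seed: int = 0, n_genes: int = 500) -> RunConfig:
    """RunConfig scaled to the bundled synthetic data.

    The atlas-default QC thresholds assume transcriptome-wide gene
    counts; simulated matrices are a few hundred genes, so the feature
    floor scales with the gene budget and the count ceiling is left
    permissive (dead cells are what the synthetic QC exercise targets).
    """
    return RunConfig(
        sample_id="synthetic",
        min_features=max(20, int(0.1 * n_genes)),
        max_counts=10_000_000,
        max_pct_mito=25.0,
        adaptive_mito=True,
        n_variable_genes=min(300, n_genes),
        n_pcs=20,
        knn_k=15,
        resolution=0.8,
        rng_seed=seed,
    )


def run_pipeline(adata, config: RunConfig | None = None, with_tree: bool = False) -> dict:
    """Run the standard pipeline and return a results dict.

    Keys: ``adata`` (filtered, with lognorm layer), ``qc``, ``mito_threshold``,
    ``variable_genes``, ``scaled``, ``embedding``, ``explained_variance``,
    ``labels`` and optionally ``tree``.
    """
    cfg = config or RunConfig()
    qc = compute_qc(adata)
    if cfg.adaptive_mito and len(qc) >= 100:
        try:
            mito_thr = adaptive_mito_threshold(qc["pct_mito"].to_numpy())
        except ValueError:
            mito_thr = cfg.max_pct_mito
    else:
        mito_thr = cfg.max_pct_mito
    keep = filter_cells(qc, cfg.min_features, cfg.max_counts, mito_thr)
    adata = adata[keep].copy()

    adata = log_normalize(adata, cfg.scale_factor)
    hvg = select_variable_genes_vst(adata, cfg.n_variable_genes)

    covars = {"pct_mito": qc.loc[keep, "pct_mito"].to_numpy(), "n_counts": qc.loc[keep, "n_counts"].to_numpy()}
    for key, label in (("s_phase", "S_score"), ("g2m_phase", "G2M_score")):
        try:
            gs = bundled_gene_set(key)
            covars[label] = score_gene_module(adata, gs, seed=cfg.rng_seed)
        except (ValueError, KeyError):
            logger.info("stage=score_gene_module module=%s skipped=absent_genes", key)
    scaled = regress_and_scale(adata, hvg, pd.DataFrame(covars, index=adata.obs_names))

    emb, evr = pca(scaled, cfg.n_pcs)
    labels = cluster_cells(emb, k=min(cfg.knn_k, adata.n_obs - 1), resolution=cfg.resolution, seed=cfg.rng_seed)
    adata.obs["cluster"] = labels
    adata.obsm["X_pca"] = emb

    out = {
        "adata": adata,
        "qc": qc,
        "mito_threshold": float(mito_thr),
        "variable_genes": hvg,
        "scaled": scaled,
        "embedding": emb,
        "explained_variance": evr,
        "labels": np.asarray(labels),
    }
    if with_tree and len(set(labels)) >= 2:
        tree = build_cluster_tree(emb, labels)
        out["tree"] = nodal_split_markers(tree, adata, labels)
    return out
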