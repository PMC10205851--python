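"""Normalization, variable-gene selection, module scoring, scaling, PCA.

The stage order mirrors standard scRNA-seq practice: counts are
log-normalized per cell (ln(1 + count * scale_factor / cell_total),
scale factor 10,000), 2,000 variable genes are chosen by the
variance-stabilizing-transform criterion, S and G2M cell-cycle module
scores are computed from the normalized layer, then variable genes are
regressed against technical/cycle covariates and z-scored (clipped at
+/-10) before a 20-dimensional PCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._log import logger
from .genesets import GeneSet

LAYER_LOGNORM = "lognorm"


def log_normalize(adata, scale_factor: float = 10000.0, layer: str = LAYER_LOGNORM):
    """Add a log-normalized layer: ln(1 + count * scale_factor / cell_total).

    Sparsity is preserved (zero counts stay exactly zero).  Cells with a
    zero total are an error: they should have been removed by QC.
    """
    X = sp.csr_matrix(adata.X, copy=True).astype(np.float64)
    totals = np.asarray(X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = int((totals <= 0).sum())
        raise ValueError(f"{bad} cell(s) have zero total counts; filter before normalizing")
    scale = scale_factor / totals
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)
    adata.layers[layer] = X.tocsr()
    logger.info("stage=log_normalize scale_factor=%g n_cells=%d", scale_factor, adata.n_obs)
    return adata


def select_variable_genes_vst(adata, n: int = 2000, loess_span: float = 0.3) -> GeneSet:
    """Top-n variable genes by VST standardized variance on raw counts.

    Fits a lowess curve of log10(variance) against log10(mean), predicts
    each gene's expected standard deviation, clips the standardized
    values at sqrt(n_cells) and ranks genes by the variance of the
    clipped z-scores.  Ties break by gene order (deterministic).
    """
    X = sp.csr_matrix(adata.X)
    n_cells = adata.n_obs
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = X.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=0)).ravel()
    var = (ex2 - mean**2) * n_cells / max(n_cells - 1, 1)

    ok = (mean > 0) & (var > 0)
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise ValueError("no genes with positive variance")
    if n > n_ok:
        logger.warning("requested %d variable genes but only %d qualify; returning all", n, n_ok)
        n = n_ok

    lx, ly = np.log10(mean[ok]), np.log10(var[ok])
    if np.unique(lx).size < 3:  # degenerate: identical mean structure
        fitted = np.full_like(lx, ly.mean())
    else:
        fit = lowess(ly, lx, frac=loess_span, return_sorted=True)
        fitted = np.interp(lx, fit[:, 0], fit[:, 1])
    exp_sd = np.sqrt(10.0**fitted)

    clip = np.sqrt(n_cells)
    std_var = np.zeros(adata.n_vars)
    Xc = X.tocsc()
    idx_ok = np.flatnonzero(ok)
    # variance of clipped z-scores, computed sparsely: zeros contribute (-mu/sd)
    for pos, j in enumerate(idx_ok):
        col = Xc.data[Xc.indptr[j] : Xc.indptr[j + 1]]
        mu, sd = mean[j], exp_sd[pos]
        z_nz = np.clip((col - mu) / sd, -clip, clip)
        z_zero = np.clip(-mu / sd, -clip, clip)
        n_zero = n_cells - col.size
        s1 = z_nz.sum() + n_zero * z_zero
        s2 = (z_nz**2).sum() + n_zero * z_zero**2
        std_var[j] = (s2 - s1**2 / n_cells) / max(n_cells - 1, 1)

    order = np.lexsort((np.arange(adata.n_vars), -std_var))
    genes = [adata.var_names[i] for i in order[:n]]
    adata.var["vst_standardized_variance"] = std_var
    adata.var["highly_variable"] = False
    adata.var.loc[genes, "highly_variable"] = True
    logger.info("stage=select_variable_genes_vst n=%d", len(genes))
    return GeneSet("variable_genes", tuple(genes), source="vst")


def score_gene_module(
    adata,
    genes: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    layer: str = LAYER_LOGNORM,
) -> np.ndarray:
    """Binned-control module score per cell (mean(module) - mean(controls)).

    Genes are binned by their dataset-average expression (``n_bins``
    equal-frequency bins); for every module gene ``n_ctrl`` control
    genes are drawn from its bin with a seeded RNG.  Used for the S and
    G2M cell-cycle scores.
    """
    if layer not in adata.layers:
        raise KeyError(f"layer {layer!r} missing; run log_normalize first")
    present = [g for g in genes if g in adata.var_names]
    if not present:
        raise ValueError(f"none of the module genes are in the matrix: {list(genes)[:10]}...")
    X = sp.csr_matrix(adata.layers[layer])
    avg = np.asarray(X.mean(axis=0)).ravel()
    ranks = pd.Series(avg, index=adata.var_names).rank(method="first")
    bins = pd.cut(ranks, bins=n_bins, labels=False)

    rng = np.random.default_rng(seed)
    var_index = pd.Index(adata.var_names)
    ctrl: set[str] = set()
    for g in present:
        b = bins.loc[g]
        pool = var_index[bins.values == b].difference(present)
        if len(pool) == 0:
            continue
        take = min(n_ctrl, len(pool))
        ctrl.update(rng.choice(pool, size=take, replace=False))
    ctrl_list = sorted(ctrl)
    mod_idx = var_index.get_indexer(present)
    mod_mean = np.asarray(X[:, mod_idx].mean(axis=1)).ravel()
    if ctrl_list:
        ctrl_idx = var_index.get_indexer(ctrl_list)
        ctrl_mean = np.asarray(X[:, ctrl_idx].mean(axis=1)).ravel()
    else:
        ctrl_mean = np.zeros(adata.n_obs)
    score = mod_mean - ctrl_mean
    logger.info("stage=score_gene_module module=%s n_genes=%d n_ctrl=%d", genes.name, len(present), len(ctrl_list))
    return score


@dataclass
class ScaledMatrix:
    """Dense covariate-regressed z-scores for the variable genes.

    Per retained gene the values are OLS residuals against the covariate
    design (with intercept), standardized to mean 0 / variance 1 and
    clipped symmetrically at ``clip``.
    """

    genes: tuple[str, ...]
    values: np.ndarray  # cells x genes
    covariates: tuple[str, ...]
    clip: float
    obs_names: tuple[str, ...] = field(default=())

    def gene_values(self, gene: str) -> np.ndarray:
        gene = gene.upper()
        if gene not in self.genes:
            raise KeyError(f"gene {gene!r} not in scaled matrix")
        return self.values[:, self.genes.index(gene)]


def regress_and_scale(
    adata,
    genes: GeneSet | None = None,
    covariates: pd.DataFrame | None = None,
    clip: float = 10.0,
    layer: str = LAYER_LOGNORM,
) -> ScaledMatrix:
    """Regress covariates out of the normalized layer, z-score and clip.

    ``covariates`` columns (e.g. pct_mito, n_counts, S score, G2M score)
    are centered and used in a single OLS design with intercept;
    collinear columns are dropped with a warning based on the design's
    condition number.
    """
    gene_list = list(genes) if genes is not None else list(adata.var_names)
    idx = [adata.var_names.get_loc(g) for g in gene_list if g in adata.var_names]
    Y = np.asarray(sp.csr_matrix(adata.layers[layer])[:, idx].todense(), dtype=float)
    n_cells = Y.shape[0]

    names: list[str] = []
    cols = [np.ones(n_cells)]
    if covariates is not None and covariates.shape[1] > 0:
        C = covariates.to_numpy(dtype=float)
        if not np.isfinite(C).all():
            raise ValueError("covariates contain non-finite values")
        C = C - C.mean(axis=0)
        for k, colname in enumerate(covariates.columns):
            cand = np.column_stack(cols + [C[:, k]])
            if np.linalg.cond(cand) > 1e10 or np.allclose(C[:, k], 0):
                logger.warning("dropping collinear/constant covariate %r", colname)
                continue
            cols.append(C[:, k])
            names.append(str(colname))
    X = np.column_stack(cols)

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sd = resid.std(axis=0, ddof=1)
    # genes fit exactly by the covariates have (numerically) zero residual
    # variance; their scaled rows are identically zero, not amplified noise
    exact = sd <= 1e-10 * np.maximum(Y.std(axis=0, ddof=1), 1.0)
    sd[exact] = 1.0
    resid[:, exact] = 0.0
    Z = resid / sd
    Z = np.clip(Z, -clip, clip)
    logger.info(
        "stage=regress_and_scale n_genes=%d covariates=%s clip=%g",
        Z.shape[1], ",".join(names) or "none", clip,
    )
    kept = tuple(g for g in gene_list if g in adata.var_names)
    return ScaledMatrix(kept, Z, tuple(names), clip, tuple(adata.obs_names))


def pca(scaled: ScaledMatrix, n_dims: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the scaled matrix; returns (embedding, explained_variance_ratio).

    Component signs are fixed so each component's largest-magnitude
    loading is positive, making reruns bitwise reproducible.
    """
    from sklearn.decomposition import PCA

    max_dims = min(scaled.values.shape) - 1
    if n_dims > max_dims:
        logger.warning("n_dims=%d too large; clamping to %d", n_dims, max_dims)
        n_dims = max_dims
    model = PCA(n_components=n_dims, svd_solver="full")
    emb = model.fit_transform(scaled.values)
    flip = np.sign(model.components_[np.arange(n_dims), np.abs(model.components_).argmax(axis=1)])
    flip[flip == 0] = 1.0
    emb = emb * flip
    logger.info("stage=pca n_dims=%d evr1=%.3f", n_dims, model.explained_variance_ratio_[0])
    return emb, model.explained_variance_ratio_
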