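"""Cancer-stem-cell sum scoring and Markov-chain signaling entropy.

Two complementary stemness readouts:

* **CSC sum score** — per cluster, the sum over a marker vignette (40
  established cancer-stem-cell genes by default) of the cluster-mean
  normalized expression; clusters are ranked descending.

* **Signaling entropy rate (SR)** — a cell's expression vector x is
  overlaid on a PPI network W to define a random walk with transitions
  p_ij = W_ij x_j / sum_k W_ik x_k: from gene i the walk prefers
  neighbours that are highly expressed.  Its stationary distribution has
  the closed form pi_i ~ x_i (Wx)_i (detailed balance holds because W is
  symmetric).  The entropy rate sum_i pi_i S_i, with local entropies
  S_i = -sum_j p_ij ln p_ij, is normalized by ln lambda_max(W) — the
  maximal entropy rate attainable on the network — giving SR in [0, 1].
  Diffuse (stem-like) expression spreads the walk and pushes SR toward
  1; expression concentrated on few pathways prunes the walk and lowers
  SR.  All logarithms are natural.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from ._log import logger
from .genesets import GeneSet
from .ppi import PPINetwork


@dataclass
class CSCScore:
    per_cell: pd.Series  # sum of normalized expression over markers, per cell
    per_cluster: pd.Series  # sum over markers of cluster-mean expression
    ranking: list[str]  # clusters, descending score
    n_markers_used: int
    n_markers_missing: int


def cluster_csc_score(adata, labels, markers: GeneSet, layer: str = "lognorm") -> CSCScore:
    """Sum-total marker expression per cluster, with descending ranking.

    Markers absent from the matrix contribute 0 (a count is logged);
    if no marker is present at all this is an error.
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    present = [g for g in markers if g in adata.var_names]
    missing = len(markers) - len(present)
    if not present:
        raise ValueError(f"no marker of {markers.name!r} present in the matrix")
    if missing:
        logger.warning("%d/%d CSC markers absent from matrix; contributing 0", missing, len(markers))
    X = sp.csr_matrix(adata.layers[layer]) if layer in adata.layers else sp.csr_matrix(adata.X)
    idx = [adata.var_names.get_loc(g) for g in present]
    per_cell = pd.Series(np.asarray(X[:, idx].sum(axis=1)).ravel(), index=adata.obs_names)
    per_cluster = (
        pd.DataFrame(np.asarray(X[:, idx].todense()), index=adata.obs_names)
        .groupby(labels, sort=True)
        .mean()
        .sum(axis=1)
    )
    ranking = per_cluster.sort_values(ascending=False, kind="mergesort").index.tolist()
    logger.info("stage=cluster_csc_score n_markers=%d top=%s", len(present), ranking[0])
    return CSCScore(per_cell, per_cluster, ranking, len(present), missing)


@dataclass
class EntropyResult:
    """Signaling-entropy output for one cell or a batch.

    ``sr`` is the normalized rate in [0, 1]; ``raw_rate`` is in nats;
    ``stationary_residual`` is the l1 residual of pi P = pi, a numerical
    diagnostic that should sit at machine precision.
    """

    sr: np.ndarray
    raw_rate: np.ndarray
    lambda_max: float
    n_network_genes: int
    stationary_residual: np.ndarray
    failed: np.ndarray | None = None


def _effective_network(network: PPINetwork, gene_index: pd.Index) -> tuple[PPINetwork, np.ndarray]:
    """Restrict the network to measured genes, then to its largest component."""
    measured = [g for g in network.genes if g in gene_index]
    if len(measured) < 2:
        raise ValueError("fewer than 2 network genes are measured in the matrix")
    sub = network.subset(measured)
    comps = sub.component_sizes()
    if len(comps) > 1:
        logger.warning(
            "network disconnected after intersection (component sizes %s); using largest",
            comps,
        )
        sub = sub.largest_component()
    elif not sub.is_largest_component:
        sub = PPINetwork(sub.genes, sub.adjacency, is_largest_component=True)
    idx = gene_index.get_indexer(list(sub.genes))
    return sub, idx


def _pseudocount(x: np.ndarray) -> float:
    pos = x[x > 0]
    if pos.size == 0:
        return 1e-8
    return max(1e-8, 1e-3 * float(pos.min()))


def signaling_entropy(x: np.ndarray, network: PPINetwork) -> EntropyResult:
    """Signaling entropy rate of one cell (explicit dense chain).

    ``x`` is the expression of ``network.genes`` in that order; zeros are
    lifted by a small pseudocount so the chain is irreducible.  Kept as
    an explicit-matrix reference path; use :func:`batch_entropy` for
    many cells.
    """
    if not network.is_largest_component and len(network.component_sizes()) > 1:
        raise ValueError(
            f"network has {len(network.component_sizes())} components; "
            "restrict to the largest connected component first"
        )
    x = np.asarray(x, dtype=float).ravel()
    if x.size != network.n_genes:
        raise ValueError(f"expression length {x.size} != network size {network.n_genes}")
    x = np.maximum(x, _pseudocount(x))
    W = network.adjacency.toarray()
    lam = network.lambda_max()
    if lam <= 1.0:
        raise ValueError(f"lambda_max={lam:.4f} <= 1: ln-normalization undefined on this network")

    wx = W @ x
    P = (W * x[None, :]) / wx[:, None]
    pi = x * wx
    pi = pi / pi.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    S = -(P * logP).sum(axis=1)
    raw = float(pi @ S)
    sr = raw / np.log(lam)
    resid = float(np.abs(pi @ P - pi).sum())
    return EntropyResult(
        sr=np.array([sr]),
        raw_rate=np.array([raw]),
        lambda_max=lam,
        n_network_genes=network.n_genes,
        stationary_residual=np.array([resid]),
    )


def batch_entropy(adata, network: PPINetwork, layer: str = "lognorm") -> EntropyResult:
    """Vectorized signaling entropy for every cell of a matrix.

    Restricts the network to genes measured in the matrix (largest
    connected component), computes lambda_max once, and evaluates the
    per-cell rate with sparse matrix algebra:

        S_i = ln((Wx)_i) - [ (W o ln W) x + W (x o ln x) ]_i / (Wx)_i

    Cells whose computation fails (e.g. all-zero on the network) are
    flagged, not fatal.
    """
    sub, idx = _effective_network(network, pd.Index(adata.var_names))
    lam = sub.lambda_max()
    if lam <= 1.0:
        raise ValueError(f"lambda_max={lam:.4f} <= 1: ln-normalization undefined on this network")
    X = sp.csr_matrix(adata.layers[layer]) if layer in adata.layers else sp.csr_matrix(adata.X)
    E = np.asarray(X[:, idx].todense(), dtype=float)  # cells x network genes

    W = sub.adjacency
    WlnW = W.copy()
    WlnW.data = W.data * np.log(W.data)

    n_cells = E.shape[0]
    sr = np.full(n_cells, np.nan)
    raw = np.full(n_cells, np.nan)
    resid = np.full(n_cells, np.nan)
    failed = np.zeros(n_cells, dtype=bool)

    eps = np.array([_pseudocount(E[c]) for c in range(n_cells)])
    Xp = np.maximum(E, eps[:, None]).T  # genes x cells, strictly positive

    A = W @ Xp  # (Wx)_i per cell
    B = WlnW @ Xp + W @ (Xp * np.log(Xp))
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.log(A) - B / A
    Pi = Xp * A
    Pi = Pi / Pi.sum(axis=0, keepdims=True)
    raw_all = (Pi * S).sum(axis=0)
    sr_all = raw_all / np.log(lam)

    ok = np.isfinite(sr_all)
    sr[ok], raw[ok] = sr_all[ok], raw_all[ok]
    failed[~ok] = True
    if failed.any():
        logger.warning("batch_entropy: %d cell(s) failed and are flagged", int(failed.sum()))

    # stationary residual diagnostic ||pi P - pi||_1 per cell
    # pi P = (x o Wx) P / Z; computed columnwise
    for c in np.flatnonzero(ok):
        x = Xp[:, c]
        pi = Pi[:, c]
        piP = ((pi / A[:, c]) @ W) * x  # row-vector times P
        resid[c] = float(np.abs(piP - pi).sum())

    logger.info("stage=batch_entropy n_cells=%d n_genes=%d lambda_max=%.4f", n_cells, sub.n_genes, lam)
    return EntropyResult(sr, raw, lam, sub.n_genes, resid, failed)


def entropy_gene_correlation(adata, sr: np.ndarray, layer: str = "lognorm", alpha: float = 0.05) -> pd.DataFrame:
    """Spearman correlation of every gene with the entropy score.

    Bonferroni-corrected over genes tested; each gene is classified
    positive / negative / null at adjusted alpha.  Genes with constant
    expression have undefined rho and are flagged null.
    """
    sr = np.asarray(sr, dtype=float).ravel()
    n = sr.size
    if n < 10:
        raise ValueError(f"need >=10 cells for the correlation (got {n})")
    X = sp.csr_matrix(adata.layers[layer]) if layer in adata.layers else sp.csr_matrix(adata.X)
    E = np.asarray(X.todense(), dtype=float)

    r_sr = rankdata(sr)
    ranks = np.apply_along_axis(rankdata, 0, E)
    const = np.ptp(E, axis=0) == 0

    rc = ranks - ranks.mean(axis=0)
    sc = r_sr - r_sr.mean()
    denom = np.sqrt((rc**2).sum(axis=0) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(denom > 0, (rc * sc[:, None]).sum(axis=0) / denom, np.nan)
    rho[const] = np.nan

    # t-approximation, as in scipy.stats.spearmanr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(np.abs(t), df=n - 2)
    p[const] = np.nan
    n_tested = int((~const).sum())
    padj = np.minimum(p * n_tested, 1.0)

    sign = np.where(
        const | ~(padj < alpha), "null", np.where(rho > 0, "positive", "negative")
    )
    out = pd.DataFrame(
        {
            "gene": list(adata.var_names),
            "rho": rho,
            "p": p,
            "p_adj": padj,
            "classification": sign,
            "constant": const,
        }
    )
    logger.info(
        "stage=entropy_gene_correlation n_genes=%d n_positive=%d n_negative=%d",
        len(out), int((sign == "positive").sum()), int((sign == "negative").sum()),
    )
    return out
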