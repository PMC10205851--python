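"""Wilcoxon rank-sum marker tables and the pct-difference gene-vector filter.

A marker record carries, per gene: the two-sided rank-sum p-value, its
Bonferroni adjustment, avg_log2FC (log2 ratio of de-logged means with
pseudocount 1), pct.1 / pct.2 (the fraction of cells expressing the gene
inside vs outside the tested group) and their difference.  A cluster's
"gene vector" is the table filtered for strictly avg_log2FC > 0.8 and
difference > 0.5: genes with a large expressing-fraction difference are
the most direct representation of the cluster's state.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from ._log import logger
from .io import MARKER_COLUMNS

# Groups at or below this size per side use the exact permutation null of
# the rank-sum statistic (handles ties via midranks); larger groups use
# the asymptotic normal approximation with tie correction.
EXACT_MAX_GROUP = 10


def _exact_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact permutation p of the rank-sum of the first group.

    Enumerates all C(n, n1) assignments of the observed (mid)ranks and
    counts assignments whose rank-sum is at least as extreme (two-sided,
    distance from the mean rank-sum) as observed.
    """
    n = ranks.size
    observed = ranks[:n1].sum()
    mu = n1 * (n + 1) / 2.0
    obs_dev = abs(observed - mu) - 1e-12  # tolerate float midranks
    count = 0
    for idx in combinations(range(n), n1):
        s = ranks[list(idx)].sum()
        if abs(s - mu) >= obs_dev:
            count += 1
    return count / comb(n, n1)


def _asymptotic_ranksum_p(rank_sum: float, n1: int, n2: int, tie_term: float) -> float:
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (rank_sum - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def wilcoxon_markers(
    adata,
    labels: pd.Series | np.ndarray,
    group: str,
    reference: str = "rest",
    layer: str = "lognorm",
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Marker table for one group vs the rest (or another group).

    Expression comes from the log-normalized layer; pct.1/pct.2 come from
    the positivity mask (value > 0), which is identical on raw counts.
    p-values are Bonferroni-adjusted over the genes tested; rows sort by
    p, then |avg_log2FC|, then gene symbol.
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    in_mask = (labels == str(group)).to_numpy()
    out_mask = ~in_mask if reference == "rest" else (labels == str(reference)).to_numpy()
    n1, n2 = int(in_mask.sum()), int(out_mask.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError(f"empty group: in={n1}, reference={n2}")
    if n1 < 3 or n2 < 3:
        raise ValueError(f"both groups need >=3 cells (got {n1}, {n2})")

    X = sp.csr_matrix(adata.layers[layer]) if layer in adata.layers else sp.csr_matrix(adata.X)
    if genes is not None:
        idx = [adata.var_names.get_loc(g) for g in genes if g in adata.var_names]
        gene_names = [adata.var_names[i] for i in idx]
    else:
        idx = list(range(adata.n_vars))
        gene_names = list(adata.var_names)
    Xin = np.asarray(X[in_mask][:, idx].todense())
    Xout = np.asarray(X[out_mask][:, idx].todense())

    pct1 = (Xin > 0).mean(axis=0)
    pct2 = (Xout > 0).mean(axis=0)
    mean_in = np.expm1(Xin).mean(axis=0)
    mean_out = np.expm1(Xout).mean(axis=0)
    log2fc = np.log2((mean_in + 1.0) / (mean_out + 1.0))

    use_exact = max(n1, n2) <= EXACT_MAX_GROUP
    pvals = np.empty(len(idx))
    for j in range(len(idx)):
        vals = np.concatenate([Xin[:, j], Xout[:, j]])
        ranks = rankdata(vals)
        if np.ptp(vals) == 0:
            pvals[j] = 1.0
        elif use_exact:
            pvals[j] = _exact_ranksum_p(ranks, n1)
        else:
            _, tie_counts = np.unique(vals, return_counts=True)
            tie_term = float((tie_counts**3 - tie_counts).sum())
            pvals[j] = _asymptotic_ranksum_p(ranks[:n1].sum(), n1, n2, tie_term)

    padj = np.minimum(pvals * len(idx), 1.0)
    df = pd.DataFrame(
        {
            "gene": gene_names,
            "p_val": pvals,
            "p_val_adj": padj,
            "avg_log2FC": log2fc,
            "pct.1": pct1,
            "pct.2": pct2,
            "difference": pct1 - pct2,
            "cluster": str(group),
        }
    )
    df = df.sort_values(
        by=["p_val", "avg_log2FC", "gene"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "avg_log2FC" else s,
        kind="mergesort",
    ).reset_index(drop=True)
    logger.info("stage=wilcoxon_markers group=%s n1=%d n2=%d n_genes=%d exact=%s", group, n1, n2, len(idx), use_exact)
    return df[MARKER_COLUMNS]


def filter_gene_vector(
    records: pd.DataFrame,
    min_log2fc: float = 0.8,
    min_difference: float = 0.5,
) -> pd.DataFrame:
    """Strict gene-vector filter: avg_log2FC > 0.8 AND difference > 0.5.

    Both inequalities are strict; row order is preserved; an empty result
    is allowed.  Idempotent.
    """
    keep = (records["avg_log2FC"] > min_log2fc) & (records["difference"] > min_difference)
    return records.loc[keep].reset_index(drop=True)
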