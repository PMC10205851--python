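"""Receptor-status subtyping of clusters from ESR1 / PGR / ERBB2 expression.

Receptor expression in single cells is bimodal: a detected-expression
mode and an overexpression mode, split at a scaled value of 0.25.  A
cluster counts as *overexpressing* a receptor when the expressing
fraction exceeds 0.5 and the mean expression exceeds 0.5 (consistent and
significant expression in the population); it is *positive* when at
least half the cells clear the threshold, and *negative* otherwise.
Subtype assignment: ERBB2 overexpression -> HER2+; otherwise hormone
receptor (ESR1 or PGR) at least positive -> Luminal; otherwise TNBC.
Samples whose clusters disagree get a composite label such as
"HER2+ & TNBC".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._log import logger

RECEPTORS = ("ESR1", "PGR", "ERBB2")
BIMODALITY_THRESHOLD = 0.25
STATUS_ORDER = {"negative": 0, "positive": 1, "overexpressed": 2}
SUBTYPE_ORDER = ("HER2+", "Luminal", "TNBC")


def _gene_values(adata, gene: str, layer: str) -> np.ndarray:
    """Per-cell values of one gene on the requested layer.

    ``scaled`` z-scores the log-normalized values of that gene across
    cells (so receptors need not be part of the variable-gene subset);
    ``lognorm`` returns the normalized values directly.
    """
    gene = gene.upper()
    if gene not in adata.var_names:
        near = [g for g in adata.var_names if g.startswith(gene[:3])][:5]
        raise KeyError(f"gene {gene!r} not in matrix; nearest symbols: {near}")
    base = "lognorm" if "lognorm" in adata.layers else None
    X = sp.csr_matrix(adata.layers[base]) if base else sp.csr_matrix(adata.X)
    v = np.asarray(X[:, adata.var_names.get_loc(gene)].todense()).ravel().astype(float)
    if layer == "scaled":
        sd = v.std(ddof=1)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    return v


def receptor_positivity(
    adata,
    gene: str,
    labels=None,
    threshold: float = BIMODALITY_THRESHOLD,
    layer: str = "scaled",
) -> tuple[np.ndarray, pd.Series]:
    """Per-cell positivity (value > threshold) and per-cluster pct_above."""
    v = _gene_values(adata, gene, layer)
    positive = v > threshold
    if labels is None:
        labels = np.zeros(adata.n_obs, dtype=object)
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    pct_above = pd.Series(positive, index=adata.obs_names).groupby(labels, sort=True).mean()
    return positive, pct_above


def cluster_receptor_status(pct_above: float, mean_expr: float) -> str:
    """Status of one receptor in one cluster.

    overexpressed iff pct_above > 0.5 and mean_expr > 0.5;
    else positive iff pct_above >= 0.5; else negative.
    """
    if pct_above > 0.5 and mean_expr > 0.5:
        return "overexpressed"
    if pct_above >= 0.5:
        return "positive"
    return "negative"


def assign_subtype(statuses: dict[str, str]) -> str:
    """Subtype from the three receptor statuses.

    HER2+ iff ERBB2 is overexpressed; else Luminal iff ESR1 or PGR is at
    least positive; else TNBC.
    """
    for r in RECEPTORS:
        if statuses.get(r) not in STATUS_ORDER:
            raise ValueError(f"missing or invalid status for {r}: {statuses.get(r)!r}")
    if statuses["ERBB2"] == "overexpressed":
        return "HER2+"
    if STATUS_ORDER[statuses["ESR1"]] >= 1 or STATUS_ORDER[statuses["PGR"]] >= 1:
        return "Luminal"
    return "TNBC"


def composite_sample_label(subtypes: list[str]) -> str:
    """Unique subtypes joined in fixed order (HER2+, Luminal, TNBC)."""
    if not subtypes:
        raise ValueError("need at least one cluster subtype")
    uniq = set(subtypes)
    bad = uniq - set(SUBTYPE_ORDER)
    if bad:
        raise ValueError(f"unknown subtype label(s): {sorted(bad)}")
    return " & ".join(s for s in SUBTYPE_ORDER if s in uniq)


@dataclass
class SubtypeCall:
    cluster: str
    receptor_pct: dict[str, float]
    receptor_mean: dict[str, float]
    receptor_status: dict[str, str]
    subtype: str


def call_subtypes(
    adata,
    labels,
    threshold: float = BIMODALITY_THRESHOLD,
    layer: str = "scaled",
) -> pd.DataFrame:
    """Full per-cluster subtype report.

    For each cluster and receptor: the fraction of cells above the
    bimodality threshold, the mean expression on the chosen layer, the
    derived status, and the cluster subtype.  The layer used is recorded
    in the table attrs.
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    clusters = sorted(labels.unique())
    per_receptor: dict[str, tuple[pd.Series, pd.Series]] = {}
    for r in RECEPTORS:
        v = _gene_values(adata, r, layer)
        vals = pd.Series(v, index=adata.obs_names)
        pct = (vals > threshold).groupby(labels, sort=True).mean()
        mean = vals.groupby(labels, sort=True).mean()
        per_receptor[r] = (pct, mean)

    rows = []
    for c in clusters:
        statuses = {}
        row: dict[str, object] = {"cluster": c}
        for r in RECEPTORS:
            pct, mean = per_receptor[r]
            statuses[r] = cluster_receptor_status(float(pct[c]), float(mean[c]))
            row[f"{r}_pct"] = float(pct[c])
            row[f"{r}_mean"] = float(mean[c])
            row[f"{r}_status"] = statuses[r]
        row["subtype"] = assign_subtype(statuses)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["layer"] = layer
    out.attrs["threshold"] = threshold
    logger.info("stage=call_subtypes n_clusters=%d subtypes=%s", len(clusters), out["subtype"].tolist())
    return out
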