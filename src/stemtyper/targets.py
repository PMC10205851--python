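"""Therapeutic target prediction from subtype-specific gene vectors.

The chain: genes expressed in the HER2+ population at pct > 0.4 are
anti-joined against genes expressed at pct > 0.2 in the non-HER2+
population (removing anything the contrast group also expresses),
ribosomal and mitochondrial symbols are stripped, and the remainder is
intersected with the surfaceome and an FDA-approved-target catalog to
yield candidate (gene, drug) hits.  A separate per-cluster response
predictor flags clusters in which both a drug's target gene and its
inhibition-pathway genes are expressed above a floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._log import logger
from .genesets import GeneSet

RIBO_MITO_PREFIXES = ("RPL", "RPS", "MRPL", "MRPS", "MT-")


def expressed_genes(adata, labels, group, min_pct: float = 0.25, genes=None, name: str | None = None) -> GeneSet:
    """Genes expressed (count > 0) in strictly more than ``min_pct`` of the group's cells."""
    if not (0 < min_pct < 1):
        raise ValueError(f"min_pct must lie in (0,1), got {min_pct}")
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    mask = (labels == str(group)).to_numpy()
    if not mask.any():
        raise ValueError(f"group {group!r} has no cells")
    X = sp.csr_matrix(adata.X)[mask]
    # integer count then divide: keeps boundary fractions (e.g. 25/100) exact
    frac = np.asarray((X > 0).sum(axis=0)).ravel() / X.shape[0]
    keep = frac > min_pct
    if genes is not None:
        allowed = {g.upper() for g in genes}
        keep &= np.array([g in allowed for g in adata.var_names])
    symbols = [g for g, k in zip(adata.var_names, keep) if k]
    if not symbols:
        raise ValueError(f"no genes exceed pct {min_pct} in group {group!r}")
    return GeneSet(name or f"expressed_{group}_pct{min_pct}", tuple(symbols), source="expressed_genes")


def subtype_contrast_vector(her2_expressed: GeneSet, nonher2_expressed: GeneSet) -> GeneSet:
    """Anti-join: HER2+ expressed set minus the non-HER2+ expressed set.

    Order is preserved from the HER2+ set.
    """
    return GeneSet(
        "her2_contrast",
        tuple(g for g in her2_expressed if g not in set(nonher2_expressed.genes)),
        source=f"{her2_expressed.name} \\ {nonher2_expressed.name}",
    )


def strip_ribo_mito(genes: GeneSet) -> GeneSet:
    """Remove ribosomal (RPL/RPS/MRPL/MRPS) and mitochondrial (MT-) symbols."""
    kept = tuple(g for g in genes if not g.upper().startswith(RIBO_MITO_PREFIXES))
    removed = len(genes) - len(kept)
    if removed:
        logger.info("stage=strip_ribo_mito removed=%d kept=%d", removed, len(kept))
    return GeneSet(genes.name, kept, genes.source)


@dataclass
class TargetHit:
    gene: str
    on_surfaceome: bool
    fda_target: bool
    drugs: tuple[str, ...] = ()
    clusters_expressing: dict[str, float] = field(default_factory=dict)
    subtype_specificity: str = ""


def read_fda_catalog(path: str | Path) -> dict[str, list[str]]:
    """Read a TSV catalog with columns gene, drug[, approval_note] -> {gene: [drugs]}."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    if "gene" not in cols or "drug" not in cols:
        raise ValueError(f"FDA catalog {path} needs 'gene' and 'drug' columns")
    catalog: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        catalog.setdefault(str(row[cols["gene"]]).upper(), []).append(str(row[cols["drug"]]))
    return catalog


def intersect_catalogs(
    genes: GeneSet,
    surfaceome: GeneSet,
    fda_catalog: dict[str, list[str]] | None = None,
    subtype: str = "",
) -> list[TargetHit]:
    """One TargetHit per input gene found on the surfaceome.

    The FDA flag and drug names attach when the gene is in the catalog.
    """
    if len(surfaceome) == 0:
        raise ValueError("surfaceome is empty")
    surface = set(surfaceome.genes)
    fda_catalog = fda_catalog or {}
    hits = [
        TargetHit(
            gene=g,
            on_surfaceome=True,
            fda_target=g in fda_catalog,
            drugs=tuple(fda_catalog.get(g, ())),
            subtype_specificity=subtype,
        )
        for g in genes
        if g in surface
    ]
    logger.info(
        "stage=intersect_catalogs n_in=%d n_surface=%d n_fda=%d subtype=%s",
        len(genes), len(hits), sum(h.fda_target for h in hits), subtype or "-",
    )
    return hits


def predict_response(
    adata,
    labels,
    target_gene: str,
    pathway_genes: GeneSet,
    min_target_pct: float = 0.25,
    min_pathway_pct: float = 0.25,
) -> pd.DataFrame:
    """Per-cluster responder call for a (target, inhibition-pathway) pair.

    A cluster is flagged responder when the target gene's expressing
    fraction exceeds ``min_target_pct`` and at least half of the pathway
    genes exceed ``min_pathway_pct``.  A rationale string explains each
    call.
    """
    target_gene = target_gene.upper()
    if target_gene not in adata.var_names:
        raise KeyError(f"target gene {target_gene!r} not in matrix")
    present = [g for g in pathway_genes if g in adata.var_names]
    if not present:
        raise ValueError(f"no pathway gene of {pathway_genes.name!r} present in matrix")
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    X = sp.csr_matrix(adata.X)
    pos = pd.DataFrame(
        np.asarray((X[:, [adata.var_names.get_loc(g) for g in [target_gene] + present]] > 0).todense()),
        index=adata.obs_names,
        columns=[target_gene] + present,
    )
    frac = pos.groupby(labels, sort=True).mean()

    rows = []
    for c in frac.index:
        t_pct = float(frac.loc[c, target_gene])
        path_ok = [g for g in present if frac.loc[c, g] > min_pathway_pct]
        responder = (t_pct > min_target_pct) and (len(path_ok) >= len(present) / 2.0)
        if responder:
            why = f"targeted successfully: {target_gene} expressed in {t_pct:.0%} of cells with pathway support ({len(path_ok)}/{len(present)} genes)"
        elif t_pct > min_target_pct:
            low = sorted(set(present) - set(path_ok))
            why = f"less effective: {target_gene} expressed but low expression of pathway gene(s) {', '.join(low)}"
        else:
            why = f"not targeted: {target_gene} expressed in only {t_pct:.0%} of cells"
        rows.append({"cluster": c, "target_pct": t_pct, "n_pathway_above": len(path_ok), "n_pathway": len(present), "responder": responder, "rationale": why})
    out = pd.DataFrame(rows)
    logger.info("stage=predict_response target=%s n_responders=%d", target_gene, int(out["responder"].sum()))
    return out
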