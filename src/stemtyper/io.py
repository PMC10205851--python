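"""Readers and writers for 10x-style count matrices and marker tables.

On disk a count matrix is the 10x triplet dialect: ``matrix.mtx[.gz]``
(Matrix Market coordinate, genes as rows, cells as columns, 1-based),
``features.tsv[.gz]`` (1, 2 or 3 columns; gene symbol in the first or
second column) and ``barcodes.tsv[.gz]``.  In memory it is an
:class:`anndata.AnnData` with cells as observations and genes as
variables, raw counts in ``X`` (sparse) and derived layers added by the
preprocessing stages.  Orientation on disk is detected from the features
file length, so transposed matrices read correctly.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from ._log import logger

MARKER_COLUMNS = ["gene", "p_val", "p_val_adj", "avg_log2FC", "pct.1", "pct.2", "difference", "cluster"]


def _find(dirpath: Path, stem: str) -> Path:
    for cand in (dirpath / f"{stem}.tsv", dirpath / f"{stem}.tsv.gz", dirpath / f"{stem}.txt"):
        if cand.exists():
            return cand
    # 10x v2 naming for features
    if stem == "features":
        for cand in (dirpath / "genes.tsv", dirpath / "genes.tsv.gz"):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"missing {stem} file in {dirpath}")


def _find_mtx(dirpath: Path) -> Path:
    for cand in (dirpath / "matrix.mtx", dirpath / "matrix.mtx.gz"):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"missing matrix.mtx[.gz] in {dirpath}")


def _read_tsv_lines(path: Path) -> list[list[str]]:
    op = gzip.open if str(path).endswith(".gz") else open
    with op(path, "rt") as fh:
        return [ln.rstrip("\n").split("\t") for ln in fh if ln.strip()]


def deduplicate_symbols(symbols: list[str]) -> list[str]:
    """Deterministically deduplicate: repeats get '.1', '.2', ... suffixes."""
    counts: dict[str, int] = {}
    out = []
    for s in symbols:
        if s in counts:
            counts[s] += 1
            out.append(f"{s}.{counts[s]}")
        else:
            counts[s] = 0
            out.append(s)
    return out


def read_count_matrix(path: str | Path) -> ad.AnnData:
    """Read a 10x-dialect count matrix directory into AnnData (cells x genes).

    Gene symbols are uppercased and deduplicated with '.1'/'.2' suffixes.
    The on-disk orientation (genes x cells vs cells x genes) is detected
    from the features-file line count; either reads to the same object.
    """
    dirpath = Path(path)
    if not dirpath.is_dir():
        raise FileNotFoundError(f"count matrix directory not found: {dirpath}")
    mtx_path = _find_mtx(dirpath)
    feat_path = _find(dirpath, "features")
    bc_path = _find(dirpath, "barcodes")

    mat = sp.csr_matrix(mmread(str(mtx_path)))
    feats = _read_tsv_lines(feat_path)
    bcs = [row[0] for row in _read_tsv_lines(bc_path)]

    # 10x features file: 1 column (symbol), 2 (id, symbol) or 3 (id, symbol, type)
    if feats and len(feats[0]) >= 2:
        symbols = [row[1] for row in feats]
        gene_ids = [row[0] for row in feats]
    else:
        symbols = [row[0] for row in feats]
        gene_ids = symbols[:]

    n_feat, n_bc = len(feats), len(bcs)
    if mat.shape == (n_feat, n_bc):
        genes_by_cells = mat
    elif mat.shape == (n_bc, n_feat):
        genes_by_cells = mat.T.tocsr()
    else:
        raise ValueError(
            f"dimension mismatch in {dirpath}: matrix {mat.shape}, "
            f"{n_feat} features, {n_bc} barcodes"
        )

    symbols = deduplicate_symbols([s.upper() for s in symbols])
    adata = ad.AnnData(
        X=genes_by_cells.T.tocsr().astype(np.float64),
        obs=pd.DataFrame(index=pd.Index(bcs, name="barcode")),
        var=pd.DataFrame({"gene_id": gene_ids}, index=pd.Index(symbols, name="gene")),
    )
    logger.info("stage=read_count_matrix path=%s n_cells=%d n_genes=%d", dirpath, adata.n_obs, adata.n_vars)
    return adata


def write_count_matrix(adata: ad.AnnData, path: str | Path) -> None:
    """Write AnnData raw counts as a 10x triplet directory (genes x cells)."""
    dirpath = Path(path)
    dirpath.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(adata.X.T)  # genes x cells on disk
    mmwrite(str(dirpath / "matrix.mtx"), X, field="integer" if _is_integral(X) else "real")
    gene_ids = adata.var["gene_id"] if "gene_id" in adata.var else adata.var_names
    with open(dirpath / "features.tsv", "w") as fh:
        for gid, sym in zip(gene_ids, adata.var_names):
            fh.write(f"{gid}\t{sym}\tGene Expression\n")
    with open(dirpath / "barcodes.tsv", "w") as fh:
        fh.write("\n".join(adata.obs_names) + "\n")
    logger.info("stage=write_count_matrix path=%s n_cells=%d n_genes=%d", dirpath, adata.n_obs, adata.n_vars)


def _is_integral(X: sp.spmatrix) -> bool:
    return bool(np.all(np.mod(X.data, 1) == 0)) if X.nnz else True


def merge_counts(adatas: list[ad.AnnData], sample_ids: list[str] | None = None) -> ad.AnnData:
    """Merge samples into one atlas on the union of barcodes (inner gene join).

    Barcodes are prefixed with their sample id to stay unique; the merged
    cell count equals the sum of the component counts.
    """
    if sample_ids is None:
        sample_ids = [f"sample{i}" for i in range(len(adatas))]
    keyed = []
    for sid, a in zip(sample_ids, adatas):
        b = a.copy()
        b.obs_names = [f"{sid}:{bc}" for bc in b.obs_names]
        b.obs["sample_id"] = sid
        keyed.append(b)
    merged = ad.concat(keyed, join="inner", merge="first")
    assert merged.n_obs == sum(a.n_obs for a in adatas)
    logger.info("stage=merge_counts n_samples=%d n_cells=%d", len(adatas), merged.n_obs)
    return merged


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a marker table TSV with the canonical column schema."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "cluster": str})
    missing = [c for c in MARKER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"marker table {path} missing columns: {missing}")
    return df[MARKER_COLUMNS]


def write_marker_table(df: pd.DataFrame, path: str | Path) -> None:
    df[MARKER_COLUMNS].to_csv(path, sep="\t", index=False)
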