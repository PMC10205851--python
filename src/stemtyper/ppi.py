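"""Protein–protein interaction networks as weighted symmetric adjacencies.

The network is stored as a symmetric, non-negative, zero-diagonal sparse
adjacency over uppercase gene symbols.  The largest-connected-component
restriction and the dominant adjacency eigenvalue (lambda_max, whose
natural log is the maximal attainable entropy rate of any random walk on
the network) are exposed here because the signaling-entropy scorer needs
both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from ._log import logger


@dataclass
class PPINetwork:
    genes: tuple[str, ...]
    adjacency: sp.csr_matrix  # symmetric, non-negative, zero diagonal
    is_largest_component: bool = False
    _lambda_max: float | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        A = sp.csr_matrix(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.genes):
            raise ValueError("adjacency shape does not match gene list")
        if A.diagonal().any():
            A = A - sp.diags(A.diagonal())
        if (A.data < 0).any():
            raise ValueError("negative edge weights are not allowed")
        asym = abs(A - A.T)
        if asym.nnz and asym.max() > 1e-12:
            raise ValueError("adjacency must be symmetric")
        A.eliminate_zeros()
        self.adjacency = A

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return self.adjacency.nnz // 2

    def degrees(self) -> np.ndarray:
        return np.asarray((self.adjacency > 0).sum(axis=1)).ravel()

    def component_sizes(self) -> list[int]:
        n, labels = connected_components(self.adjacency, directed=False)
        return sorted(np.bincount(labels).tolist(), reverse=True)

    def largest_component(self) -> "PPINetwork":
        """Restrict to the largest connected component (ties: first label)."""
        n, labels = connected_components(self.adjacency, directed=False)
        if n == 1:
            return PPINetwork(self.genes, self.adjacency, is_largest_component=True)
        sizes = np.bincount(labels)
        keep = np.flatnonzero(labels == sizes.argmax())
        sub = self.adjacency[np.ix_(keep, keep)]
        return PPINetwork(tuple(self.genes[i] for i in keep), sp.csr_matrix(sub), is_largest_component=True)

    def subset(self, genes: Iterable[str]) -> "PPINetwork":
        """Restrict to the given genes (order from this network)."""
        keep_set = {g.upper() for g in genes}
        idx = [i for i, g in enumerate(self.genes) if g in keep_set]
        if not idx:
            raise ValueError("gene subset shares no symbols with the network")
        sub = self.adjacency[np.ix_(idx, idx)]
        return PPINetwork(tuple(self.genes[i] for i in idx), sp.csr_matrix(sub))

    def lambda_max(self) -> float:
        """Largest eigenvalue of the (weighted) adjacency, cached."""
        if self._lambda_max is None:
            A = self.adjacency
            if A.shape[0] <= 64:
                self._lambda_max = float(np.linalg.eigvalsh(A.toarray()).max())
            else:
                val = sp.linalg.eigsh(A, k=1, which="LA", return_eigenvectors=False)
                self._lambda_max = float(val[0])
        return self._lambda_max


def ppi_from_edges(
    edges: Sequence[tuple[str, str] | tuple[str, str, float]],
    duplicate_rule: str = "max",
) -> PPINetwork:
    """Build a network from (geneA, geneB[, weight]) records.

    Self-loops are dropped with a warning; duplicate edges are resolved by
    taking the maximum weight (conservative connectivity).  Missing
    weights default to 1.
    """
    best: dict[tuple[str, str], float] = {}
    n_self = 0
    for rec in edges:
        a, b = str(rec[0]).upper(), str(rec[1]).upper()
        w = float(rec[2]) if len(rec) > 2 and rec[2] is not None else 1.0
        if w < 0:
            raise ValueError(f"negative weight on edge {a}-{b}: {w}")
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if duplicate_rule == "max":
            best[key] = max(best.get(key, -np.inf), w)
        else:
            best[key] = w
    if n_self:
        logger.warning("dropped %d self-loop edge(s)", n_self)
    if not best:
        raise ValueError("edge list contains no usable edges")
    genes = tuple(sorted({g for pair in best for g in pair}))
    index = {g: i for i, g in enumerate(genes)}
    rows, cols, vals = [], [], []
    for (a, b), w in best.items():
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
        vals += [w, w]
    A = sp.csr_matrix((vals, (rows, cols)), shape=(len(genes), len(genes)))
    net = PPINetwork(genes, A)
    logger.info(
        "stage=read_ppi n_genes=%d n_edges=%d largest_cc=%d",
        net.n_genes, net.n_edges, net.component_sizes()[0],
    )
    return net


def read_ppi(path: str | Path) -> PPINetwork:
    """Read a PPI edge list TSV: geneA, geneB, optional weight (default 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PPI edge list not found: {path}")
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for ln in fh:
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed PPI line in {path}: {ln!r}")
            w = float(parts[2]) if len(parts) > 2 and parts[2] != "" else 1.0
            edges.append((parts[0], parts[1], w))
    return ppi_from_edges(edges)


def write_ppi(net: PPINetwork, path: str | Path) -> None:
    A = sp.triu(sp.coo_matrix(net.adjacency), k=1).tocoo()
    with open(path, "w") as fh:
        for i, j, w in zip(A.row, A.col, A.data):
            fh.write(f"{net.genes[i]}\t{net.genes[j]}\t{w:g}\n")
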