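"""SNN-graph clustering and cluster trees with nodal-split gene vectors.

Cells are clustered on the PCA embedding: a k-nearest-neighbour graph is
reweighted by shared-neighbour (Jaccard) overlap, weakly overlapping
edges are pruned, and modularity-based (Louvain-family, Leiden) community
detection is run at the configured resolution.  Cluster relationships
are then summarized as a dendrogram over "average cells" (per-cluster
centroids in PCA space, average linkage), and every internal node of the
tree gets a marker table of the left vs right branch — the nodal-split
gene vectors that describe which genes drive each population divergence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import linkage, to_tree
from sklearn.neighbors import NearestNeighbors

from ._log import logger
from .markers import filter_gene_vector, wilcoxon_markers

SNN_PRUNE = 1.0 / 15.0  # minimum Jaccard overlap kept in the SNN graph


def snn_graph(embedding: np.ndarray, k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbour graph: Jaccard overlap of kNN sets, pruned."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean").fit(embedding)
    knn = nn.kneighbors_graph(embedding, mode="connectivity")
    knn = knn.maximum(sp.eye(n, format="csr"))  # each cell neighbours itself
    shared = knn @ knn.T  # |N(i) & N(j)| since rows are 0/1
    shared = sp.coo_matrix(shared)
    sizes = np.asarray(knn.sum(axis=1)).ravel()
    union = sizes[shared.row] + sizes[shared.col] - shared.data
    jac = shared.data / union
    keep = (jac >= SNN_PRUNE) & (shared.row != shared.col)
    W = sp.csr_matrix((jac[keep], (shared.row[keep], shared.col[keep])), shape=(n, n))
    return W


def cluster_cells(
    embedding: np.ndarray,
    k: int = 20,
    resolution: float = 0.8,
    seed: int = 0,
) -> np.ndarray:
    """Leiden community detection on the SNN graph; labels "0","1",...

    Labels are ordered by decreasing cluster size, ties by first
    occurrence, so reruns with one seed are identical.
    """
    W = snn_graph(embedding, k)
    coo = sp.triu(sp.coo_matrix(W.maximum(W.T)), k=1)
    g = igraph.Graph(
        n=W.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    raw = np.asarray(part.membership)
    uniq, first_idx = np.unique(raw, return_index=True)
    sizes = np.bincount(raw)
    order = uniq[np.lexsort((first_idx, -sizes[uniq]))]
    remap = {old: str(new) for new, old in enumerate(order)}
    labels = np.array([remap[c] for c in raw], dtype=object)
    logger.info("stage=cluster_cells k=%d resolution=%g n_clusters=%d", k, resolution, len(order))
    return labels


@dataclass
class TreeNode:
    """One node of the cluster dendrogram."""

    members: tuple[str, ...]  # cluster labels under this node
    height: float
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    left_markers: pd.DataFrame | None = field(default=None, repr=False)
    right_markers: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None


@dataclass
class ClusterTree:
    """Binary dendrogram over cluster labels, built on average cells."""

    root: TreeNode
    leaves: tuple[str, ...]
    space: str = "pca"  # distance space used for the average cells

    def internal_nodes(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if not node.is_leaf:
                out.append(node)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_h: float) -> str:
            length = max(parent_h - node.height, 0.0)
            if node.is_leaf:
                return f"{node.members[0]}:{length:g}"
            return f"({fmt(node.left, node.height)},{fmt(node.right, node.height)}):{length:g}"

        return fmt(self.root, self.root.height) + ";"

    def cumulative_gene_vector(self, cluster: str) -> pd.DataFrame:
        """Concatenated ancestral nodal vectors for one cluster.

        Walking root-to-leaf, at every internal node take the filtered
        marker table of the branch containing the cluster; the
        concatenation (root split first) is the cluster's cumulative
        gene vector.
        """
        if cluster not in self.leaves:
            raise KeyError(f"cluster {cluster!r} not in tree leaves {self.leaves}")
        frames: list[pd.DataFrame] = []
        node = self.root
        while not node.is_leaf:
            if cluster in node.left.members:
                if node.left_markers is not None:
                    frames.append(node.left_markers)
                node = node.left
            else:
                if node.right_markers is not None:
                    frames.append(node.right_markers)
                node = node.right
        if not frames:
            return pd.DataFrame(columns=["gene", "p_val", "p_val_adj", "avg_log2FC", "pct.1", "pct.2", "difference", "cluster"])
        out = pd.concat(frames, ignore_index=True)
        return out.drop_duplicates(subset="gene", keep="first").reset_index(drop=True)


def build_cluster_tree(embedding: np.ndarray, labels: np.ndarray, space: str = "pca") -> ClusterTree:
    """Average-linkage dendrogram over per-cluster average cells.

    The "average cell" of a cluster is its centroid in PCA space;
    clusters merge by average-linkage Euclidean distance.  Leaf order is
    deterministic (scipy's ordering on the sorted label list).
    """
    labels = np.asarray(labels).astype(str)
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValueError("cluster tree needs at least 2 clusters")
    centroids = np.vstack([embedding[labels == c].mean(axis=0) for c in uniq])
    Z = linkage(centroids, method="average", metric="euclidean")
    scipy_root = to_tree(Z)

    def convert(sn) -> TreeNode:
        if sn.is_leaf():
            return TreeNode(members=(uniq[sn.id],), height=0.0)
        left, right = convert(sn.left), convert(sn.right)
        return TreeNode(members=left.members + right.members, height=float(sn.dist), left=left, right=right)

    root = convert(scipy_root)
    logger.info("stage=build_cluster_tree n_clusters=%d space=%s", len(uniq), space)
    return ClusterTree(root=root, leaves=tuple(uniq), space=space)


def _mirror_markers(left: pd.DataFrame, group_label: str) -> pd.DataFrame:
    """Marker table of the opposite branch, derived by symmetry.

    The two-sided rank-sum p is direction-free, so the right-branch table
    is the left one with fold change negated and pct.1/pct.2 swapped.
    """
    out = left.copy()
    out["avg_log2FC"] = -out["avg_log2FC"]
    out[["pct.1", "pct.2"]] = out[["pct.2", "pct.1"]].to_numpy()
    out["difference"] = out["pct.1"] - out["pct.2"]
    out["cluster"] = group_label
    return out.sort_values(
        by=["p_val", "avg_log2FC", "gene"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "avg_log2FC" else s,
        kind="mergesort",
    ).reset_index(drop=True)


def nodal_split_markers(
    tree: ClusterTree,
    adata,
    labels: np.ndarray,
    layer: str = "lognorm",
    min_log2fc: float = 0.8,
    min_difference: float = 0.5,
) -> ClusterTree:
    """Attach filtered left/right marker vectors to every internal node.

    At each node the cells under the left branch are tested against the
    cells under the right branch with the Wilcoxon rank-sum test, and
    the result is passed through the strict gene-vector filter.
    """
    labels = pd.Series(np.asarray(labels).astype(str), index=adata.obs_names)
    if set(tree.leaves) != set(labels.unique()):
        raise ValueError("tree leaves do not match the provided labels")
    for node in tree.internal_nodes():
        branch = labels.map(
            lambda c: "left" if c in node.left.members else ("right" if c in node.right.members else "other")
        )
        sub = adata[branch != "other"]
        table = wilcoxon_markers(sub, branch[branch != "other"], group="left", reference="right", layer=layer)
        left_label = "+".join(node.left.members)
        right_label = "+".join(node.right.members)
        left = table.copy()
        left["cluster"] = left_label
        node.left_markers = filter_gene_vector(left, min_log2fc, min_difference)
        node.right_markers = filter_gene_vector(_mirror_markers(table, right_label), min_log2fc, min_difference)
    return tree
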