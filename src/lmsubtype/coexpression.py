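"""Co-expression gene modules and unsupervised sample clustering.

Genes with high expression variance are linked when their pairwise Pearson
correlation exceeds a threshold; communities of the resulting graph
(Girvan-Newman edge betweenness, cut at maximum modularity) are the
co-expression modules. Samples are then clustered on the module genes with
a PCA -> Ward -> k-means-consolidation procedure mirroring the HCPC
approach of FactoMineR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import girvan_newman, modularity
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModule",
    "ClusteringResult",
    "build_coexpression_graph",
    "detect_communities",
    "cluster_samples",
]


@dataclass
class GeneModule:
    module_id: str
    genes: list
    flagged: bool  # carries at least ``min_size`` genes

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class ClusteringResult:
    labels: pd.Series  # per-sample cluster id (1-based)
    n_components_retained: int
    linkage_heights: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.nunique())


def build_coexpression_graph(
    m: pd.DataFrame, var_min: float = 2.0, pcc_min: float = 0.7
) -> nx.Graph:
    """Build the gene co-expression graph.

    Nodes are genes with sample variance (ddof=1) above ``var_min`` on the
    log2 scale of the input; an undirected edge joins two genes whose
    Pearson correlation exceeds ``pcc_min``. No self loops.
    """
    if m.shape[1] < 2:
        raise ValueError("need at least 2 samples to compute variance")
    variances = m.var(axis=1, ddof=1)
    keep = variances > var_min
    g = nx.Graph()
    if not keep.any():
        logger.warning("no gene passes the variance filter (> %g); empty graph", var_min)
        return g
    genes = list(m.index[keep])
    g.add_nodes_from(genes)
    x = m.loc[genes].to_numpy(dtype=float)
    cc = np.corrcoef(x)
    iu, ju = np.triu_indices(len(genes), k=1)
    hit = cc[iu, ju] > pcc_min
    g.add_edges_from((genes[i], genes[j]) for i, j in zip(iu[hit], ju[hit]))
    return g


def detect_communities(g: nx.Graph, min_size: int = 5) -> list[GeneModule]:
    """Girvan-Newman community detection, cut at maximum modularity.

    Edge-betweenness edges are removed iteratively; along the resulting
    dendrogram of partitions the one with maximal modularity is kept (the
    connected-components partition included). All communities are returned,
    with ``flagged=True`` for those carrying at least ``min_size`` genes.
    Deterministic under sorted node order; ties broken toward the
    first-encountered (coarsest) partition.
    """
    if g.number_of_nodes() == 0:
        return []
    # relabel through sorted order for deterministic betweenness tie-breaks
    nodes = sorted(g.nodes())
    base = [sorted(c) for c in nx.connected_components(g)]
    base.sort()
    best, best_q = base, _modularity(g, base)
    if g.number_of_edges() > 0:
        for partition in girvan_newman(g):
            part = sorted(sorted(c) for c in partition)
            q = _modularity(g, part)
            if q > best_q + 1e-12:
                best, best_q = part, q
            if len(part) >= len(nodes):
                break
    modules = []
    for i, genes in enumerate(sorted(best, key=lambda c: (-len(c), c)), start=1):
        modules.append(
            GeneModule(module_id=f"M{i:02d}", genes=list(genes), flagged=len(genes) >= min_size)
        )
    return modules


def _modularity(g: nx.Graph, partition) -> float:
    if g.number_of_edges() == 0:
        return 0.0
    return modularity(g, partition)


def cluster_samples(
    m: pd.DataFrame,
    feature_genes: list | None = None,
    var_explained: float = 0.95,
    max_clusters: int = 10,
    consolidate: bool = True,
) -> ClusteringResult:
    """Cluster samples on the co-expression feature genes, HCPC style.

    PCA on the feature submatrix (samples as observations, centered,
    unscaled); the smallest number of components explaining at least
    ``var_explained`` of the variance is retained. Ward-linkage hierarchical
    clustering on the component scores follows; the tree is cut at the
    number of clusters with the largest relative loss of within-cluster
    inertia between successive merges, and a single k-means pass initialized
    at the cluster means consolidates the partition.
    """
    if m.shape[1] < 3:
        raise ValueError("need at least 3 samples to cluster")
    if feature_genes is not None:
        missing = [g for g in feature_genes if g not in m.index]
        if missing:
            raise KeyError(f"feature genes absent from matrix: {missing[:5]}")
        m = m.loc[list(feature_genes)]
    x = m.to_numpy(dtype=float).T  # samples x genes
    n = x.shape[0]
    if np.allclose(x, x[0]):  # degenerate: identical samples
        return ClusteringResult(
            labels=pd.Series(1, index=m.columns), n_components_retained=0
        )
    pca = PCA(n_components=min(n - 1, x.shape[1]), svd_solver="full")
    scores = pca.fit_transform(x - x.mean(axis=0))
    cum = np.cumsum(pca.explained_variance_ratio_)
    ncomp = int(np.searchsorted(cum, var_explained) + 1)
    ncomp = min(ncomp, scores.shape[1])
    scores = scores[:, :ncomp]

    z = linkage(scores, method="ward")
    heights = z[:, 2]
    k = _inertia_gap_k(heights, max_clusters=min(max_clusters, n - 1))
    labels = fcluster(z, t=k, criterion="maxclust")

    if consolidate and k > 1:
        means = np.vstack([scores[labels == c].mean(axis=0) for c in np.unique(labels)])
        km = KMeans(n_clusters=k, init=means, n_init=1, max_iter=1, random_state=0)
        labels = km.fit_predict(scores) + 1
    return ClusteringResult(
        labels=pd.Series(labels, index=m.columns),
        n_components_retained=ncomp,
        linkage_heights=heights,
    )


def _inertia_gap_k(heights: np.ndarray, max_clusters: int) -> int:
    """Choose the cut level by maximum relative inertia loss.

    ``heights[-k]`` is the within-inertia gain absorbed when going from
    k+1 to k clusters; cutting at k is attractive when that merge is much
    more expensive than the next one, i.e. heights[-(k-1)]/heights[-k]
    is large. k ranges over 2..max_clusters.
    """
    n_merges = len(heights)
    best_k, best_ratio = 2, -np.inf
    for k in range(2, max(3, min(max_clusters, n_merges) + 1)):
        merge_to_k = heights[n_merges - (k - 1)]  # cost of merging k -> k-1 clusters
        merge_below = heights[n_merges - k] if n_merges - k >= 0 else np.nan
        if not np.isfinite(merge_below) or merge_below <= 0:
            continue
        ratio = merge_to_k / merge_below
        if ratio > best_ratio + 1e-12:
            best_k, best_ratio = k, ratio
    return best_k
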