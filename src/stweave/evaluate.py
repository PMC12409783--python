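"""Clustering, ARI scoring, marker detection, and MIA enrichment.

Embeddings are clustered with seeded k-means (cluster counts are fixed
to match annotations in benchmark use, so no resolution search is
needed); fused affinity graphs with spectral clustering, with a Leiden
resolution-bisection fallback.  Agreement with ground truth is scored
by the adjusted Rand index.  Marker genes are Wilcoxon rank-sum tests
per cluster with Benjamini-Hochberg correction; multimodal intersection
analysis (MIA) scores the overlap of cluster markers with cell-type
marker sets by hypergeometric tails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import hypergeom, mannwhitneyu
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .core_data import EmbeddingSet
from .integration import FusedGraph


@dataclass
class ClusterResult:
    labels: np.ndarray
    K: int
    method: str
    seed: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.K < 1:
            raise ValueError("K must be >= 1")


def cluster_embeddings(emb: EmbeddingSet, K: int, seed: int = 0) -> ClusterResult:
    """Seeded k-means (10 restarts, best inertia kept)."""
    if K < 1:
        raise ValueError("K must be >= 1")
    n = emb.matrix.shape[0]
    if K > n:
        raise ValueError(f"K={K} exceeds n={n}")
    km = KMeans(n_clusters=K, n_init=10, random_state=seed % (2**31))
    return ClusterResult(labels=km.fit_predict(emb.matrix), K=K,
                         method="kmeans", seed=seed)


def _leiden_bisect(A: sparse.csr_matrix, K: int, seed: int, max_steps: int = 30):
    """Leiden community detection, bisecting the resolution until the
    cluster count hits K (nearest count kept after max_steps)."""
    import igraph as ig
    import leidenalg

    src, dst = A.nonzero()
    keep = src < dst
    g = ig.Graph(n=A.shape[0], edges=list(zip(src[keep], dst[keep])))
    weights = np.asarray(A[src[keep], dst[keep]]).ravel()

    def run(res):
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            weights=weights.tolist(), resolution_parameter=res, seed=seed % (2**31))
        return np.array(part.membership)

    lo, hi = 1e-4, 50.0
    best = None
    for _ in range(max_steps):
        mid = np.sqrt(lo * hi)
        lab = run(mid)
        ncl = lab.max() + 1
        if best is None or abs(ncl - K) < abs(best[1] - K):
            best = (lab, ncl)
        if ncl == K:
            return lab
        if ncl < K:
            lo = mid
        else:
            hi = mid
    warnings.warn(f"Leiden bisection reached {best[1]} clusters, wanted {K}")
    return best[0]


def cluster_graph(graph: FusedGraph, K: int, seed: int = 0,
                  method: str = "spectral") -> ClusterResult:
    """Cluster a fused affinity graph into K groups.

    Spectral clustering on the symmetrized affinity matrix by default;
    ``method="leiden"`` switches to Leiden with resolution bisection.
    On a disconnected graph the components are reported, the largest is
    clustered into K - (#components - 1) groups and each remaining
    component becomes its own cluster.
    """
    A = graph.to_matrix(symmetrize=True)
    n = A.shape[0]
    As = sparse.csr_matrix(A)
    n_comp, comp = connected_components(As, directed=False)
    if n_comp > 1:
        warnings.warn(f"fused graph has {n_comp} connected components; "
                      "clustering the largest")
        sizes = np.bincount(comp)
        main = np.argmax(sizes)
        mask = comp == main
        if K - (n_comp - 1) < 1:
            raise ValueError("more components than requested clusters")
        sub = FusedGraph(edges=np.array([[i, j] for i, j in graph.edges
                                         if mask[i] and mask[j]]),
                         affinities=np.array([a for (i, j), a in
                                              zip(graph.edges, graph.affinities)
                                              if mask[i] and mask[j]]),
                         weights=graph.weights, n_spots=n)
        sub_res = cluster_graph_dense(sub.to_matrix()[np.ix_(mask, mask)],
                                      K - (n_comp - 1), seed, method)
        labels = np.empty(n, dtype=int)
        labels[mask] = sub_res
        nxt = K - (n_comp - 1)
        for c in range(n_comp):
            if c != main:
                labels[comp == c] = nxt
                nxt += 1
        return ClusterResult(labels=labels, K=K, method=method, seed=seed)
    labels = cluster_graph_dense(A, K, seed, method)
    return ClusterResult(labels=labels, K=K, method=method, seed=seed)


def cluster_graph_dense(A: np.ndarray, K: int, seed: int, method: str) -> np.ndarray:
    if method == "spectral":
        sc = SpectralClustering(n_clusters=K, affinity="precomputed",
                                random_state=seed % (2**31), assign_labels="kmeans")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sc.fit_predict(A)
    if method == "leiden":
        return _leiden_bisect(sparse.csr_matrix(A), K, seed)
    raise ValueError(f"unknown graph clustering method {method!r}")


def ari(labels_a, labels_b) -> float:
    """Adjusted Rand index between two partitions (symmetric,
    label-permutation invariant; 1 = identical, 0 = chance)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError(f"label vectors differ in length: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 items")
    return float(adjusted_rand_score(a, b))


def marker_score(expression: np.ndarray, labels: np.ndarray,
                 alpha: float = 0.05, feature_names: list[str] | None = None):
    """Per-cluster ranked marker table.

    For each cluster, a two-sided Wilcoxon rank-sum test of in-cluster
    vs rest per feature, Benjamini-Hochberg adjusted; features with
    adjusted p < alpha are ranked by difference of means (descending).
    Returns {cluster: DataFrame(feature, mean_diff, p, q)}.
    """
    expression = np.asarray(expression, dtype=float)
    labels = np.asarray(labels, dtype=int)
    clusters = np.unique(labels)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    G = expression.shape[1]
    names = feature_names or [f"f{j}" for j in range(G)]
    out = {}
    for c in clusters:
        inside = expression[labels == c]
        outside = expression[labels != c]
        pvals = np.ones(G)
        for j in range(G):
            xi, xo = inside[:, j], outside[:, j]
            if np.ptp(np.concatenate([xi, xo])) == 0:  # constant feature
                continue
            pvals[j] = mannwhitneyu(xi, xo, alternative="two-sided").pvalue
        qvals = multipletests(pvals, method="fdr_bh")[1]
        diff = inside.mean(axis=0) - outside.mean(axis=0)
        df = pd.DataFrame({"feature": names, "mean_diff": diff,
                           "p": pvals, "q": qvals})
        df = df[df["q"] < alpha].sort_values("mean_diff", ascending=False)
        out[int(c)] = df.reset_index(drop=True)
    return out


def mia(cluster_markers: dict, celltype_markers: dict, universe_size: int) -> pd.DataFrame:
    """Multimodal intersection analysis: signed -log10 hypergeometric p.

    For cluster set A (|A| = a) and cell-type set B (|B| = b) in a
    universe of N genes with overlap m: enrichment p = P(X >= m),
    depletion p = P(X <= m), X ~ Hypergeom(N, a, b).  Cell value is
    -log10(enrichment p) when enrichment is the more extreme tail, else
    log10(depletion p) (depletion scores negative).  Empty sets score 0
    with a warning.
    """
    N = int(universe_size)
    rows = {}
    for cname, cset in cluster_markers.items():
        row = {}
        for tname, tset in celltype_markers.items():
            a, b = len(cset), len(tset)
            if a == 0 or b == 0:
                warnings.warn(f"empty marker set for ({cname}, {tname}); score 0")
                row[tname] = 0.0
                continue
            if a > N or b > N:
                raise ValueError("marker set larger than the universe")
            m = len(set(cset) & set(tset))
            p_enr = float(hypergeom.sf(m - 1, N, a, b))
            p_dep = float(hypergeom.cdf(m, N, a, b))
            if p_enr <= p_dep:
                row[tname] = -np.log10(max(p_enr, 1e-300))
            else:
                row[tname] = np.log10(max(p_dep, 1e-300))
        rows[cname] = row
    return pd.DataFrame(rows).T.sort_index()[sorted(celltype_markers)]
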