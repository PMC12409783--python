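"""Gene/image modality integration.

The centerpiece is per-spot weighted-nearest-neighbor (WNN) fusion: for
each spot the relative predictive power of each modality is scored by
how much better the spot's own profile is predicted by averaging its
within-modality neighbors than its cross-modality neighbors; a two-way
softmax of the scores gives per-spot modality weights in [0, 1] summing
to 1, and the fused affinity over the kNN-union edge set is the
weight-blended exponential kernel of the two modality distances.

``affinity_fuse`` is the unweighted baseline (weights pinned at 0.5) and
``concat_embed`` the naive concatenation baseline.  ``run_strategy``
executes a "+"-joined strategy string (e.g. "SME+SK+WNN") combining
spatial-aware refinement and integration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import EmbeddingSet, NeighborGraph, SpatialDataset, spatial_neighbors
from .preprocess import PreprocessConfig, filter_features, normalize_log, pca_embed, select_hvg
from .spatial_aware import SmoothingConfig, sme_smooth, spatial_kernel_refine

_EPS = 1e-12


@dataclass
class ModalityWeights:
    """Per-spot gene/image weights; each pair is in [0,1] and sums to 1."""

    w_gene: np.ndarray
    w_image: np.ndarray

    def __post_init__(self):
        self.w_gene = np.asarray(self.w_gene, dtype=float)
        self.w_image = np.asarray(self.w_image, dtype=float)
        if self.w_gene.shape != self.w_image.shape:
            raise ValueError("weight vectors must have equal length")
        if np.any(self.w_gene < 0) or np.any(self.w_image < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.w_gene + self.w_image, 1.0, atol=1e-9):
            raise ValueError("weights must sum to 1 per spot")


@dataclass
class FusedGraph:
    """Directed fused-affinity edges (i uses its own weights/bandwidths)."""

    edges: np.ndarray          # m x 2 (i, j)
    affinities: np.ndarray     # m, in [0, 1]
    weights: ModalityWeights
    n_spots: int
    provenance: str = "fused"

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int)
        self.affinities = np.asarray(self.affinities, dtype=float)
        if self.affinities.min() < 0 or self.affinities.max() > 1:
            raise ValueError("affinities must lie in [0, 1]")

    def to_matrix(self, symmetrize: bool = True) -> np.ndarray:
        """Dense affinity matrix; symmetrized by the elementwise maximum."""
        A = np.zeros((self.n_spots, self.n_spots))
        A[self.edges[:, 0], self.edges[:, 1]] = self.affinities
        if symmetrize:
            A = np.maximum(A, A.T)
        return A


def _knn(emb: np.ndarray, k: int):
    """kNN by Euclidean distance, ties broken by lower index.

    Returns (indices n x k, distance matrix n x n)."""
    n = emb.shape[0]
    D = cdist(emb, emb)
    idx = np.empty((n, k), dtype=int)
    for i in range(n):
        order = np.lexsort((np.arange(n), D[i]))
        idx[i] = order[order != i][:k]
    return idx, D


def _modality_scores(Z: np.ndarray, own_knn: np.ndarray, other_knn: np.ndarray,
                     D: np.ndarray) -> np.ndarray:
    """Relative predictive score of a modality for each spot.

    within-prediction: mean of Z over the spot's own-modality kNN;
    cross-prediction: mean of Z over its other-modality kNN;
    score = (||z - cross|| - ||z - within||) / s, with s the distance to
    the nearest within-modality neighbor (local bandwidth).
    """
    within = Z[own_knn].mean(axis=1)
    cross = Z[other_knn].mean(axis=1)
    d_within = np.linalg.norm(Z - within, axis=1)
    d_cross = np.linalg.norm(Z - cross, axis=1)
    s = D[np.arange(Z.shape[0]), own_knn[:, 0]] + _EPS
    return (d_cross - d_within) / s


def _fuse(emb_gene: EmbeddingSet, emb_image: EmbeddingSet, k_nn: int,
          w_gene: np.ndarray, provenance: str) -> FusedGraph:
    Zg, Zm = emb_gene.matrix, emb_image.matrix
    n = Zg.shape[0]
    knn_g, Dg = _knn(Zg, k_nn)
    knn_m, Dm = _knn(Zm, k_nn)
    half = int(np.ceil(k_nn / 2))
    # per-spot local bandwidth: distance to the ceil(k/2)-th within-modality neighbor
    sig_g = Dg[np.arange(n), knn_g[:, half - 1]] + _EPS
    sig_m = Dm[np.arange(n), knn_m[:, half - 1]] + _EPS
    w_image = 1.0 - w_gene
    edges, affs = [], []
    for i in range(n):
        js = np.unique(np.concatenate([knn_g[i], knn_m[i]]))
        theta = (w_gene[i] * np.exp(-Dg[i, js] / sig_g[i])
                 + w_image[i] * np.exp(-Dm[i, js] / sig_m[i]))
        edges.append(np.column_stack([np.full(js.size, i), js]))
        affs.append(theta)
    return FusedGraph(
        edges=np.vstack(edges),
        affinities=np.clip(np.concatenate(affs), 0.0, 1.0),
        weights=ModalityWeights(w_gene=w_gene, w_image=w_image),
        n_spots=n,
        provenance=provenance,
    )


def wnn_integrate(emb_gene: EmbeddingSet, emb_image: EmbeddingSet,
                  k_nn: int = 20, seed: int = 0) -> FusedGraph:
    """Weighted-nearest-neighbor fusion of two modality embeddings.

    Per-spot modality weights are the two-way softmax of each modality's
    relative predictive score (see module docstring); fused affinity over
    the kNN-union edge set is
    theta_ij = w_gene_i * exp(-d_gene(i,j)/sigma_i^g)
             + w_image_i * exp(-d_img(i,j)/sigma_i^m).
    Identical embeddings give exactly 0.5/0.5 weights.  The computation
    is deterministic; ``seed`` is accepted for interface uniformity.
    """
    del seed
    if emb_gene.matrix.shape[0] != emb_image.matrix.shape[0]:
        raise ValueError("embeddings must cover the same spots")
    n = emb_gene.matrix.shape[0]
    if k_nn < 2:
        raise ValueError("k_nn must be >= 2 (local bandwidths undefined)")
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be smaller than n={n}")
    knn_g, Dg = _knn(emb_gene.matrix, k_nn)
    knn_m, Dm = _knn(emb_image.matrix, k_nn)
    r_g = _modality_scores(emb_gene.matrix, knn_g, knn_m, Dg)
    r_m = _modality_scores(emb_image.matrix, knn_m, knn_g, Dm)
    m = np.maximum(r_g, r_m)
    eg, em = np.exp(r_g - m), np.exp(r_m - m)
    w_gene = eg / (eg + em)
    return _fuse(emb_gene, emb_image, k_nn, w_gene, provenance="WNN")


def affinity_fuse(emb_gene: EmbeddingSet, emb_image: EmbeddingSet,
                  k_nn: int = 20) -> FusedGraph:
    """Unweighted affinity fusion: WNN with both weights pinned at 0.5."""
    if emb_gene.matrix.shape[0] != emb_image.matrix.shape[0]:
        raise ValueError("embeddings must cover the same spots")
    n = emb_gene.matrix.shape[0]
    if k_nn < 2:
        raise ValueError("k_nn must be >= 2 (local bandwidths undefined)")
    if k_nn >= n:
        raise ValueError(f"k_nn={k_nn} must be smaller than n={n}")
    return _fuse(emb_gene, emb_image, k_nn, np.full(n, 0.5), provenance="FUSE")


def concat_embed(emb_gene: EmbeddingSet, emb_image: EmbeddingSet,
                 alpha: float = 0.5) -> EmbeddingSet:
    """Concatenate the standardized modality matrices, scaled alpha/(1-alpha).

    Each matrix is column-centered and divided by a single scalar (the
    square root of its total variance), preserving within-modality
    geometry while equalizing the two blocks.
    """
    if emb_gene.matrix.shape[0] != emb_image.matrix.shape[0]:
        raise ValueError("embeddings must cover the same spots")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")

    def standardize(M):
        M = M - M.mean(axis=0)
        scale = np.sqrt(M.var(axis=0).sum())
        return M / scale if scale > 0 else M

    return EmbeddingSet(
        matrix=np.hstack([alpha * standardize(emb_gene.matrix),
                          (1 - alpha) * standardize(emb_image.matrix)]),
        provenance=f"CONCAT(alpha={alpha:g})[{emb_gene.provenance}|{emb_image.provenance}]",
    )


# ---------------------------------------------------------------------------
# strategy grammar


_TOKENS = {"GENE", "IMAGE", "SME", "SK", "WNN", "FUSE", "CONCAT"}
_TERMINALS = {"WNN", "FUSE", "CONCAT"}


@dataclass
class StrategySpec:
    """A "+"-joined analysis strategy, e.g. "SME+SK+WNN".

    Token semantics (executed left to right): GENE/IMAGE select a single
    modality; SME smooths expression (morphology-weighted) before
    embedding; SK kernel-refines the current embedding(s); WNN/FUSE/
    CONCAT integrate the two modality representations and must be last.
    Without an integrator exactly one modality is used (GENE is the
    default; SME implies GENE).
    """

    tokens: list[str]
    raw: str

    @classmethod
    def parse(cls, raw: str) -> "StrategySpec":
        tokens = [t.strip().upper() for t in raw.split("+") if t.strip()]
        if not tokens:
            raise ValueError("empty strategy string")
        bad = [t for t in tokens if t not in _TOKENS]
        if bad:
            raise ValueError(
                f"unknown strategy token(s) {bad}; grammar: '+'-joined tokens "
                f"from {sorted(_TOKENS)} with at most one terminal integrator "
                "(WNN/FUSE/CONCAT) in last position"
            )
        if len(set(tokens)) != len(tokens):
            raise ValueError("repeated strategy token")
        terms = [t for t in tokens if t in _TERMINALS]
        if len(terms) > 1:
            raise ValueError("at most one integrator (WNN/FUSE/CONCAT) allowed")
        if terms and tokens[-1] not in _TERMINALS:
            raise ValueError("the integrator must be the last token")
        if not terms and "GENE" in tokens and "IMAGE" in tokens:
            raise ValueError("GENE and IMAGE together need an integrator")
        if "SME" in tokens and "IMAGE" in tokens and not terms:
            raise ValueError("SME smooths expression; combine with IMAGE only via an integrator")
        if "SME" in tokens and tokens.index("SME") != 0:
            raise ValueError("SME must precede embedding/refinement steps")
        return cls(tokens=tokens, raw="+".join(tokens))

    @property
    def terminal(self) -> str | None:
        return self.tokens[-1] if self.tokens[-1] in _TERMINALS else None


@dataclass
class StrategyParams:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    k_nn: int = 20
    alpha: float = 0.5
    sk_bandwidth: float | None = None
    neighbor_method: str = "knn"
    neighbor_k: int = 6
    seed: int = 0


def _embed_modality(matrix: np.ndarray, params: StrategyParams, provenance: str) -> EmbeddingSet:
    cfg = params.preprocess
    mat, _ = filter_features(matrix, cfg.min_frac)
    do_log = cfg.log_scale
    if do_log == "auto":
        do_log = bool(np.all(mat >= 0)) and np.any(mat > 0)
    if do_log:
        mat = normalize_log(mat, cfg.scale)
    if cfg.n_hvg != "all":
        mat, _ = select_hvg(mat, int(cfg.n_hvg))
    return pca_embed(mat, cfg.n_pcs, provenance=provenance)


def run_strategy(dataset: SpatialDataset, spec: StrategySpec | str,
                 params: StrategyParams | None = None):
    """Execute a strategy on a dataset; returns an EmbeddingSet or FusedGraph.

    Provenance of the result records the full strategy string.
    """
    if isinstance(spec, str):
        spec = StrategySpec.parse(spec)
    params = params or StrategyParams()
    tokens = set(spec.tokens)
    needs_image = bool(tokens & {"IMAGE", "SME", "WNN", "FUSE", "CONCAT"})
    if needs_image and dataset.image_features is None:
        raise ValueError(
            f"strategy {spec.raw!r} requires image features, which are absent"
        )

    graph: NeighborGraph | None = None
    if "SME" in tokens:
        graph = spatial_neighbors(dataset.coords, params.neighbor_method, params.neighbor_k)

    def gene_embedding() -> EmbeddingSet:
        expr = dataset.expression
        if "SME" in tokens:
            img_emb = _embed_modality(dataset.image_features, params, "image")
            expr = sme_smooth(expr, graph, img_emb, params.smoothing)
        return _embed_modality(expr, params, "gene" + ("+SME" if "SME" in tokens else ""))

    def image_embedding() -> EmbeddingSet:
        return _embed_modality(dataset.image_features, params, "image")

    if spec.terminal:
        eg, em = gene_embedding(), image_embedding()
        if "SK" in tokens:
            eg = spatial_kernel_refine(eg, dataset.coords, params.sk_bandwidth)
            em = spatial_kernel_refine(em, dataset.coords, params.sk_bandwidth)
        if spec.terminal == "WNN":
            out = wnn_integrate(eg, em, params.k_nn, params.seed)
        elif spec.terminal == "FUSE":
            out = affinity_fuse(eg, em, params.k_nn)
        else:
            out = concat_embed(eg, em, params.alpha)
        out.provenance = spec.raw
        return out

    emb = image_embedding() if "IMAGE" in tokens else gene_embedding()
    if "SK" in tokens:
        emb = spatial_kernel_refine(emb, dataset.coords, params.sk_bandwidth)
    emb.provenance = spec.raw
    return emb


#: mapping from names used for published strategy combinations to the
#: internal grammar (documented in docs/methods.md)
STRATEGY_ALIASES = {
    "Gene": "GENE",
    "Image": "IMAGE",
    "GeneSpatialPCA": "GENE+SK",
    "stLearn": "SME",
    "stLearn+SpatialPCA": "SME+SK",
    "WNN": "WNN",
    "SpatialPCA+WNN": "SK+WNN",
    "stLearn+WNN": "SME+WNN",
    "Concat": "CONCAT",
}
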