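"""Spatial-aware refinement of a single modality.

Two smoothers, both single-pass convex-combination operators (so output
values stay inside the local input range and constant input is a fixed
point):

* ``sme_smooth`` — SME-style morphology-weighted neighborhood smoothing
  of expression: each spot's profile is averaged with its spatial
  neighbors, weighted by rectified cosine similarity of the image
  embeddings times a Gaussian spatial decay.
* ``spatial_kernel_refine`` — Gaussian-kernel smoothing of a latent
  embedding over all spots (row-normalized kernel times the embedding),
  standing in the pipeline slot of spatially aware dimension-reduction
  methods.

An adapter slot (``similarity_to_embedding``) lets externally computed
spot-similarity matrices (e.g. from an MCMC spatial clustering) enter
the integration step in place of an embedding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import EmbeddingSet, NeighborGraph
from .utils import check_finite


@dataclass
class SmoothingConfig:
    """bandwidth: Gaussian decay scale in coordinate units (None -> the
    median nearest-neighbor distance, self-scaling across grid vs pixel
    units); morphology_floor: lower clip for the morphology weight;
    include_self: keep the spot's own profile in the average."""

    bandwidth: float | None = None
    morphology_floor: float = 0.0
    include_self: bool = True

    def __post_init__(self):
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        if self.morphology_floor < 0:
            raise ValueError("morphology_floor must be >= 0")


def _default_bandwidth(neighbors: NeighborGraph) -> float:
    nn = [w.min() for w in neighbors.weights if w.size]
    h = float(np.median(nn)) if nn else 1.0
    return h if h > 0 else 1.0


def sme_smooth(expression: np.ndarray, neighbors: NeighborGraph,
               image_emb: EmbeddingSet, config: SmoothingConfig | None = None) -> np.ndarray:
    """Morphology-weighted neighborhood smoothing of expression.

    w_ij = max(0, cos(image_emb_i, image_emb_j)) * exp(-d_ij^2 / (2 h^2))
    for j in N(i); smoothed_i = (x_i + sum_j w_ij x_j) / (1 + sum_j w_ij).
    Neighbor distances d_ij are taken from the graph weights.  Negative
    cosines are rectified to 0 so weights stay nonnegative; a spot whose
    weights all collapse to 0 is returned unchanged.
    """
    if image_emb is None:
        raise ValueError("sme_smooth requires image features (image_emb missing)")
    config = config or SmoothingConfig()
    X = check_finite("expression", expression)
    Z = image_emb.matrix
    if Z.shape[0] != X.shape[0] or neighbors.n_spots != X.shape[0]:
        raise ValueError("expression, neighbors and image_emb must cover the same spots")
    h = config.bandwidth if config.bandwidth is not None else _default_bandwidth(neighbors)
    norms = np.linalg.norm(Z, axis=1)
    out = np.empty_like(X)
    for i in range(X.shape[0]):
        nb = neighbors.neighbors[i]
        if nb.size == 0:
            out[i] = X[i]
            continue
        d = neighbors.weights[i]
        denom = norms[i] * norms[nb]
        cos = np.zeros(nb.size)
        ok = denom > 0
        cos[ok] = (Z[nb[ok]] @ Z[i]) / denom[ok]
        w = np.maximum(cos, config.morphology_floor)
        w = np.maximum(w, 0.0) * np.exp(-d**2 / (2 * h * h))
        total = w.sum()
        if config.include_self:
            out[i] = (X[i] + w @ X[nb]) / (1.0 + total)
        else:
            out[i] = (w @ X[nb]) / total if total > 0 else X[i]
    return out


def spatial_kernel_refine(emb: EmbeddingSet, coords: np.ndarray,
                          h: float | None = None) -> EmbeddingSet:
    """Gaussian-kernel smoothing of a latent embedding over space.

    K_ij = exp(-d_ij^2 / (2 h^2)); output = row-normalized K @ emb.matrix.
    As h -> 0 the kernel approaches the identity; as h -> infinity every
    row approaches the column mean.  Provenance is suffixed "+SK".
    """
    coords = check_finite("coords", coords)
    if coords.shape[0] != emb.matrix.shape[0]:
        raise ValueError("coords and embedding must cover the same spots")
    if h is None:
        D = cdist(coords, coords)
        np.fill_diagonal(D, np.inf)
        h = float(np.median(D.min(axis=1)))
    if h <= 0:
        raise ValueError("h must be positive")
    D2 = cdist(coords, coords, "sqeuclidean")
    # log-domain row normalization keeps tiny bandwidths from underflowing
    logK = -D2 / (2 * h * h)
    logK -= logK.max(axis=1, keepdims=True)
    K = np.exp(logK)
    K /= K.sum(axis=1, keepdims=True)
    return EmbeddingSet(matrix=K @ emb.matrix, provenance=emb.provenance + "+SK")


def similarity_to_embedding(similarity: np.ndarray, q: int = 20,
                            provenance: str = "external-sim") -> EmbeddingSet:
    """Adapter: turn an externally computed spot-similarity matrix into an
    embedding usable by the integration step.

    Distances are taken as 1 - similarity and embedded by classical MDS
    (eigendecomposition of the double-centered squared-distance matrix).
    """
    S = check_finite("similarity", similarity)
    if S.shape[0] != S.shape[1]:
        raise ValueError("similarity matrix must be square")
    D2 = (1.0 - S) ** 2
    n = S.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = min(q, int(np.sum(vals > 1e-10)))
    keep = max(keep, 1)
    emb = vecs[:, :keep] * np.sqrt(np.maximum(vals[:keep], 0.0))
    return EmbeddingSet(matrix=emb, provenance=provenance)
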