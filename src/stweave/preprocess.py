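"""Feature filtering, normalization, and per-modality PCA.

The same pipeline applies symmetrically to the gene and the image
modality: drop features detected in fewer than ``min_frac`` of spots
(default 1%), optionally total-count normalize + log1p (count-like data
only), optionally keep the most dispersed features, then embed to the
top ``q`` principal components (default 20), which is the working space
for integration and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import EmbeddingSet
from .utils import check_finite


@dataclass
class PreprocessConfig:
    min_frac: float = 0.01
    n_hvg: int | str = "all"
    n_pcs: int = 20
    log_scale: bool | str = "auto"  # "auto": normalize iff all entries >= 0
    scale: float = 1e4

    def __post_init__(self):
        if not 0.0 <= self.min_frac <= 1.0:
            raise ValueError("min_frac must lie in [0, 1]")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be >= 1")


def filter_features(matrix: np.ndarray, min_frac: float = 0.01):
    """Keep features that are nonzero in at least ceil(min_frac * n) spots.

    Returns (filtered matrix, kept column indices).  The ceil makes the
    threshold the strictest reading consistent with count data (1% of
    613 spots = 7 spots).
    """
    matrix = check_finite("matrix", matrix)
    n = matrix.shape[0]
    thresh = int(np.ceil(min_frac * n))
    counts = np.count_nonzero(matrix, axis=0)
    kept = np.where(counts >= thresh)[0]
    if kept.size == 0:
        raise ValueError(
            f"all {matrix.shape[1]} features removed at min_frac={min_frac}; "
            "lower min_frac"
        )
    return matrix[:, kept], kept


def normalize_log(matrix: np.ndarray, scale: float = 1e4) -> np.ndarray:
    """Total-count normalize each spot to ``scale``, then log1p.

    All-zero spots are left as zeros.  Negative entries are rejected
    (this step is for count-like data).
    """
    matrix = check_finite("matrix", matrix)
    if np.any(matrix < 0):
        raise ValueError("normalize_log requires nonnegative entries")
    totals = matrix.sum(axis=1, keepdims=True)
    safe = np.where(totals > 0, totals, 1.0)
    return np.log1p(matrix / safe * scale)


def select_hvg(matrix: np.ndarray, n_hvg: int):
    """Keep the ``n_hvg`` most dispersed features (variance/mean ratio;
    plain variance for columns with nonpositive mean)."""
    mean = matrix.mean(axis=0)
    var = matrix.var(axis=0)
    disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), var)
    if n_hvg >= matrix.shape[1]:
        return matrix, np.arange(matrix.shape[1])
    kept = np.sort(np.argsort(disp)[::-1][:n_hvg])
    return matrix[:, kept], kept


def pca_embed(matrix: np.ndarray, q: int = 20, provenance: str = "pca") -> EmbeddingSet:
    """Embed spots into the top-q principal components.

    Columns are centered; q' = min(q, rank) components are kept, ordered
    by decreasing explained variance, with a deterministic sign
    convention (the largest-magnitude loading of each component is made
    positive).
    """
    matrix = check_finite("matrix", matrix)
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots for PCA")
    X = matrix - matrix.mean(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = S[0] * max(X.shape) * np.finfo(float).eps if S.size and S[0] > 0 else 0.0
    rank = int(np.sum(S > tol))
    q_eff = max(1, min(q, rank))
    scores = U[:, :q_eff] * S[:q_eff]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(q_eff):
        a = np.argmax(np.abs(Vt[j]))
        if Vt[j, a] < 0:
            scores[:, j] = -scores[:, j]
    return EmbeddingSet(matrix=scores, provenance=provenance)


def preprocess_modality(matrix: np.ndarray, config: PreprocessConfig | None = None,
                        provenance: str = "pca") -> EmbeddingSet:
    """filter -> (normalize) -> (HVG) -> PCA, per the config."""
    config = config or PreprocessConfig()
    mat, _ = filter_features(matrix, config.min_frac)
    do_log = config.log_scale
    if do_log == "auto":
        do_log = bool(np.all(mat >= 0)) and np.any(mat > 0)
    if do_log:
        mat = normalize_log(mat, config.scale)
    if config.n_hvg != "all":
        mat, _ = select_hvg(mat, int(config.n_hvg))
    return pca_embed(mat, config.n_pcs, provenance=provenance)
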