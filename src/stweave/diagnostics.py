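"""Spatial-coherence and modality-concordance diagnostics + recommender.

Three per-dataset diagnostics, all computed on Euclidean distances in a
top-q principal-component space (similarity = negative distance):

* Average Similarity — per spot, mean similarity to its spatial
  neighbors vs an equal number of seeded random non-neighbors; the spot
  passes when neighbors are at least as similar on average.
* High-Similarity Non-Neighbor (HSNN) — per spot, the best (X) and
  median (Y) neighbor similarity vs the 95th-percentile similarity over
  all non-neighbors; a positive X gap flags spots whose most-similar
  partners are distant, i.e. exceptions to spatial locality.
* Modality Concordance — Euclidean distances of seeded random spot
  pairs in the gene vs the image PC space; a pair is discordant when it
  is among the closest 10% in one modality and the farthest 10% in the
  other.

The recommender maps the two spatial verdicts plus the concordance
verdict to one of four analysis strategies (spatial-aware processing
and/or modality integration, or plain gene-only PCA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import EmbeddingSet, NeighborGraph


class Recommendation(str, Enum):
    SPATIAL_PLUS_INTEGRATION = "SPATIAL_PLUS_INTEGRATION"
    INTEGRATION_ONLY = "INTEGRATION_ONLY"
    SPATIAL_ONLY = "SPATIAL_ONLY"
    GENE_ONLY = "GENE_ONLY"


@dataclass
class DiagnosticReport:
    avg_delta: np.ndarray | None = None
    avg_pass_frac: float = float("nan")
    hsnn_x: np.ndarray | None = None
    hsnn_y: np.ndarray | None = None
    hsnn_pass_frac: float = float("nan")
    concordance_pairs: np.ndarray | None = None  # m x 2: (dist_gene, dist_image)
    discordant_frac: float = float("nan")
    verdicts: dict = field(default_factory=dict)  # avg / hsnn / concordant booleans
    recommendation: Recommendation | None = None
    params: dict = field(default_factory=dict)

    def to_dict(self, full: bool = False) -> dict:
        out = {
            "avg_pass_frac": float(self.avg_pass_frac),
            "hsnn_pass_frac": float(self.hsnn_pass_frac),
            "discordant_frac": float(self.discordant_frac),
            "verdicts": {k: bool(v) for k, v in self.verdicts.items()},
            "recommendation": self.recommendation.value if self.recommendation else None,
            "params": self.params,
        }
        if full:
            for name in ("avg_delta", "hsnn_x", "hsnn_y"):
                v = getattr(self, name)
                out[name] = None if v is None else [float(x) for x in v]
            cp = self.concordance_pairs
            out["concordance_pairs"] = None if cp is None else np.asarray(cp).tolist()
        return out


def _non_neighbors(i: int, nb: np.ndarray, n: int) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    mask[i] = False
    mask[nb] = False
    return np.where(mask)[0]


def avg_similarity_diag(emb: EmbeddingSet, neighbors: NeighborGraph, seed: int = 0):
    """Average Similarity diagnostic.

    Sampling protocol (relied on by reproducibility): a single
    ``np.random.default_rng(seed)`` generator, spots visited in index
    order, ``rng.choice`` over the ascending non-neighbor index array,
    ``size=|N(i)|`` without replacement.  delta_i = mean distance to the
    sampled non-neighbors minus mean distance to the neighbors; the spot
    passes iff delta_i >= 0.  Returns (delta vector, pass fraction).
    """
    D = cdist(emb.matrix, emb.matrix)
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    delta = np.empty(n)
    for i in range(n):
        nb = neighbors.neighbors[i]
        if nb.size == 0:
            raise ValueError(f"spot {i} has no spatial neighbors")
        pool = _non_neighbors(i, nb, n)
        if pool.size < nb.size:
            raise ValueError(f"spot {i}: not enough non-neighbors to sample")
        samp = rng.choice(pool, size=nb.size, replace=False)
        delta[i] = D[i, samp].mean() - D[i, nb].mean()
    return delta, float(np.mean(delta >= 0))


def high_sim_nonneighbor_diag(emb: EmbeddingSet, neighbors: NeighborGraph,
                              top_frac: float = 0.05):
    """High-Similarity Non-Neighbor diagnostic.

    Per spot, with similarity = negative Euclidean distance:
    t_i = (1 - top_frac) linear-interpolation quantile of the spot's
    similarities to all non-neighbors;
    X_i = t_i - max neighbor similarity, Y_i = t_i - median neighbor
    similarity.  Spot flagged iff X_i > 0.  Returns (X, Y, pass
    fraction = 1 - flagged fraction).
    """
    if not 0.0 < top_frac < 1.0:
        raise ValueError("top_frac must lie in (0, 1)")
    S = -cdist(emb.matrix, emb.matrix)
    n = S.shape[0]
    x = np.empty(n)
    y = np.empty(n)
    for i in range(n):
        nb = neighbors.neighbors[i]
        if nb.size == 0:
            raise ValueError(f"spot {i} has no spatial neighbors")
        pool = _non_neighbors(i, nb, n)
        if pool.size == 0:
            raise ValueError(f"spot {i} has no non-neighbors")
        t = np.quantile(S[i, pool], 1.0 - top_frac)
        x[i] = t - S[i, nb].max()
        y[i] = t - np.median(S[i, nb])
    return x, y, float(np.mean(~(x > 0)))


def modality_concordance_diag(emb_gene: EmbeddingSet, emb_image: EmbeddingSet,
                              n_pairs: int = 5000, seed: int = 0,
                              corner_frac: float = 0.10, max_discordant: float = 0.05):
    """Modality Concordance diagnostic over random spot pairs.

    Samples ``n_pairs`` distinct unordered pairs (clipped with a warning
    when fewer exist) and records the pair's Euclidean distance in each
    modality's PC space.  A pair is discordant when its distance is below
    the ``corner_frac`` quantile in one modality and above the
    ``1 - corner_frac`` quantile in the other (both directions).  Verdict
    "consistent" iff the discordant fraction <= ``max_discordant``.
    Returns (pair distance table m x 2, discordant fraction, verdict).
    """
    if emb_gene.matrix.shape[0] != emb_image.matrix.shape[0]:
        raise ValueError("embeddings must cover the same spots")
    n = emb_gene.matrix.shape[0]
    total = n * (n - 1) // 2
    if n_pairs > total:
        warnings.warn(f"n_pairs={n_pairs} exceeds available {total}; clipped")
        n_pairs = total
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_pairs, replace=False)
    # decode unordered-pair index: pairs (i, j), i < j, in lexicographic order
    i = (n - 2 - np.floor(np.sqrt(-8 * flat + 4 * n * (n - 1) - 7) / 2 - 0.5)).astype(int)
    j = (flat + i + 1 - i * (2 * n - i - 1) // 2).astype(int)
    dg = np.linalg.norm(emb_gene.matrix[i] - emb_gene.matrix[j], axis=1)
    dm = np.linalg.norm(emb_image.matrix[i] - emb_image.matrix[j], axis=1)
    lo_g, hi_g = np.quantile(dg, [corner_frac, 1 - corner_frac])
    lo_m, hi_m = np.quantile(dm, [corner_frac, 1 - corner_frac])
    disc = ((dg < lo_g) & (dm > hi_m)) | ((dg > hi_g) & (dm < lo_m))
    frac = float(np.mean(disc))
    return np.column_stack([dg, dm]), frac, frac <= max_discordant


def recommend_strategy(avg_pass_frac: float, hsnn_pass_frac: float,
                       concordant: bool, pass_threshold: float = 0.90) -> Recommendation:
    """Map diagnostic verdicts to an analysis strategy.

    spatial_ok requires BOTH spatial diagnostics to pass the threshold
    (a dataset where one passes and the other fails is treated as
    spatially incoherent and routed to integration).
    """
    spatial_ok = avg_pass_frac >= pass_threshold and hsnn_pass_frac >= pass_threshold
    if spatial_ok and concordant:
        return Recommendation.SPATIAL_PLUS_INTEGRATION
    if not spatial_ok and concordant:
        return Recommendation.INTEGRATION_ONLY
    if spatial_ok and not concordant:
        return Recommendation.SPATIAL_ONLY
    return Recommendation.GENE_ONLY


def diagnose(emb_gene: EmbeddingSet, neighbors: NeighborGraph,
             emb_image: EmbeddingSet | None = None, seed: int = 0,
             top_frac: float = 0.05, n_pairs: int = 5000,
             pass_threshold: float = 0.90) -> DiagnosticReport:
    """Run all three diagnostics on the gene PC space (+ image space when
    present) and attach a strategy recommendation.

    Without image features the concordance verdict defaults to
    concordant=False semantics restricted to single-modality choices:
    the recommendation is SPATIAL_ONLY or GENE_ONLY.
    """
    delta, avg_pass = avg_similarity_diag(emb_gene, neighbors, seed=seed)
    x, y, hsnn_pass = high_sim_nonneighbor_diag(emb_gene, neighbors, top_frac=top_frac)
    report = DiagnosticReport(
        avg_delta=delta, avg_pass_frac=avg_pass,
        hsnn_x=x, hsnn_y=y, hsnn_pass_frac=hsnn_pass,
        params={"seed": seed, "top_frac": top_frac, "n_pairs": n_pairs,
                "pass_threshold": pass_threshold,
                "neighbor_method": neighbors.method,
                "q": emb_gene.q},
    )
    if emb_image is not None:
        pairs, disc, consistent = modality_concordance_diag(
            emb_gene, emb_image, n_pairs=n_pairs, seed=seed)
        report.concordance_pairs = pairs
        report.discordant_frac = disc
        report.verdicts = {"avg": avg_pass >= pass_threshold,
                           "hsnn": hsnn_pass >= pass_threshold,
                           "concordant": consistent}
        report.recommendation = recommend_strategy(avg_pass, hsnn_pass, consistent,
                                                   pass_threshold)
    else:
        spatial_ok = avg_pass >= pass_threshold and hsnn_pass >= pass_threshold
        report.verdicts = {"avg": avg_pass >= pass_threshold,
                           "hsnn": hsnn_pass >= pass_threshold,
                           "concordant": None}
        report.recommendation = (Recommendation.SPATIAL_ONLY if spatial_ok
                                 else Recommendation.GENE_ONLY)
    return report
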