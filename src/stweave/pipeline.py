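"""End-to-end pipeline: diagnose -> recommend -> run strategy -> evaluate."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core_data import SpatialDataset, spatial_neighbors
from .diagnostics import DiagnosticReport, Recommendation, diagnose
from .evaluate import ClusterResult, ari, cluster_embeddings, cluster_graph
from .integration import EmbeddingSet, FusedGraph, StrategyParams, run_strategy
from .preprocess import PreprocessConfig, preprocess_modality
from .utils import derive_seed

log = logging.getLogger("stweave")

#: recommendation -> concrete strategy string
RECOMMENDED_STRATEGY = {
    Recommendation.SPATIAL_PLUS_INTEGRATION: "SK+WNN",
    Recommendation.INTEGRATION_ONLY: "WNN",
    Recommendation.SPATIAL_ONLY: "GENE+SK",
    Recommendation.GENE_ONLY: "GENE",
}

#: fallbacks when the dataset has no image features
_NO_IMAGE_DOWNGRADE = {
    "SK+WNN": "GENE+SK",
    "WNN": "GENE",
}


@dataclass
class AutoResult:
    report: DiagnosticReport
    strategy: str
    clusters: ClusterResult
    ari: float | None


def lattice_like(coords: np.ndarray) -> bool:
    """True when coordinates sit on an integer lattice (simulated grids)."""
    return bool(np.allclose(coords, np.rint(coords)))


def default_neighbors(coords: np.ndarray, k: int = 6):
    """Package default: 4-connectivity grid graph on integer lattices,
    kNN (k=6, the hex-neighbor count of Visium arrays) otherwise."""
    if lattice_like(coords):
        return spatial_neighbors(coords, "grid", k)
    return spatial_neighbors(coords, "knn", k)


def auto_analyze(dataset: SpatialDataset, K: int, seed: int = 0,
                 params: StrategyParams | None = None,
                 preprocess: PreprocessConfig | None = None,
                 pass_threshold: float = 0.90) -> AutoResult:
    """Diagnose the dataset, pick a strategy, execute it, cluster, score.

    Diagnostics run on the gene (and, when present, image) top-q PC
    spaces.  The recommendation maps to a concrete strategy
    (see RECOMMENDED_STRATEGY); recommendations that need image
    features degrade with a logged warning when none exist.  ARI against
    the dataset's labels is reported when labels are present.
    """
    preprocess = preprocess or PreprocessConfig()
    params = params or StrategyParams(preprocess=preprocess,
                                      seed=derive_seed(seed, "strategy"))
    neighbors = default_neighbors(dataset.coords, params.neighbor_k)
    emb_gene = preprocess_modality(dataset.expression, preprocess, provenance="gene")
    emb_image = None
    if dataset.image_features is not None:
        emb_image = preprocess_modality(dataset.image_features, preprocess,
                                        provenance="image")
    report = diagnose(emb_gene, neighbors, emb_image,
                      seed=derive_seed(seed, "diagnose"),
                      pass_threshold=pass_threshold)
    strategy = RECOMMENDED_STRATEGY[report.recommendation]
    if dataset.image_features is None and strategy in _NO_IMAGE_DOWNGRADE:
        log.warning("no image features: downgrading strategy %s -> %s",
                    strategy, _NO_IMAGE_DOWNGRADE[strategy])
        strategy = _NO_IMAGE_DOWNGRADE[strategy]
    result = run_strategy(dataset, strategy, params)
    cseed = derive_seed(seed, "cluster")
    if isinstance(result, FusedGraph):
        clusters = cluster_graph(result, K, cseed)
    else:
        clusters = cluster_embeddings(result, K, cseed)
    score = ari(dataset.labels, clusters.labels) if dataset.labels is not None else None
    return AutoResult(report=report, strategy=strategy, clusters=clusters, ari=score)
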