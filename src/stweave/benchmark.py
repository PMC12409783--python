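"""Benchmark drivers: simulation suites for diagnostics and strategy ARI.

These reproduce the package's simulation study end-to-end: generate a
scenario, preprocess, run diagnostics or strategies, and aggregate over
replicates.  Used by the test suite and the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .core_data import spatial_neighbors
from .diagnostics import avg_similarity_diag, high_sim_nonneighbor_diag
from .evaluate import ari, cluster_embeddings, cluster_graph
from .integration import FusedGraph, StrategyParams, run_strategy
from .preprocess import PreprocessConfig, preprocess_modality
from .simulate import SimConfig, simulate
from .utils import derive_seed

DROPOUT_GRID = (0.6, 0.7, 0.8, 0.9)


def simulation_diagnostic_fractions(pattern: str, k: int = 10,
                                    grid=(30, 30), dropouts=DROPOUT_GRID,
                                    n_reps: int = 10, seed: int = 0) -> dict:
    """Mean spatial-diagnostic pass fractions over a simulation suite.

    For each dropout rate and replicate: simulate, embed expression to
    the top-20 PCs (after the 1% feature filter), build the lattice
    neighbor graph, and run the Average Similarity and High-Similarity
    Non-Neighbor diagnostics.  Returns mean pass fractions (in %) and
    the per-run values.
    """
    avg, hsnn = [], []
    for d in dropouts:
        for rep in range(n_reps):
            cfg = SimConfig(grid=grid, k=k, pattern=pattern, dropout=d,
                            seed=derive_seed(seed, "sim", pattern, d, rep))
            res = simulate(cfg)
            emb = preprocess_modality(res.dataset.expression, PreprocessConfig())
            graph = spatial_neighbors(res.dataset.coords, "grid")
            _, a = avg_similarity_diag(emb, graph,
                                       seed=derive_seed(seed, "diag", d, rep))
            _, _, h = high_sim_nonneighbor_diag(emb, graph)
            avg.append(a)
            hsnn.append(h)
    return {
        "avg_pass_pct": 100.0 * float(np.mean(avg)),
        "hsnn_pass_pct": 100.0 * float(np.mean(hsnn)),
        "per_run_avg": avg,
        "per_run_hsnn": hsnn,
        "n_runs": len(avg),
        "n_spots": grid[0] * grid[1],
    }


def strategy_ari(pattern: str, strategy: str, dropout: float, K: int = 10,
                 n_reps: int = 10, seed: int = 0, k_nn: int = 20) -> np.ndarray:
    """ARI against truth for one strategy over seeded replicates."""
    scores = []
    for rep in range(n_reps):
        cfg = SimConfig(pattern=pattern, dropout=dropout,
                        seed=derive_seed(seed, "sim", pattern, dropout, rep))
        res = simulate(cfg)
        params = StrategyParams(k_nn=k_nn, seed=derive_seed(seed, "strat", rep))
        result = run_strategy(res.dataset, strategy, params)
        cseed = derive_seed(seed, "cluster", strategy, rep)
        if isinstance(result, FusedGraph):
            labels = cluster_graph(result, K, cseed).labels
        else:
            labels = cluster_embeddings(result, K, cseed).labels
        scores.append(ari(res.labels, labels))
    return np.array(scores)
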