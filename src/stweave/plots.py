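"""Diagnostic and cluster-map plots (PNG, deterministic renderer settings)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

_SAVE = dict(dpi=110, metadata={"Software": "stweave"})


def plot_avg_similarity(report, out_path) -> Path:
    """Histogram of -delta per spot: bars to the positive side are spots
    more similar to random non-neighbors than to their neighbors."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    v = -np.asarray(report.avg_delta)
    ax.hist(v[v <= 0], bins=30, color="#4878cf", label="neighbors closer")
    ax.hist(v[v > 0], bins=30, color="#d65f5f", label="non-neighbors closer")
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("mean neighbor dist - mean non-neighbor dist")
    ax.set_ylabel("spots")
    ax.legend(frameon=False, fontsize=8)
    ax.set_title(f"Average Similarity (pass {report.avg_pass_frac:.1%})", fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, **_SAVE)
    plt.close(fig)
    return Path(out_path)


def plot_hsnn(report, out_path) -> Path:
    """Scatter of the HSNN X/Y statistics; flagged spots (X > 0) in red."""
    fig, ax = plt.subplots(figsize=(4, 4))
    x = np.asarray(report.hsnn_x)
    y = np.asarray(report.hsnn_y)
    flag = x > 0
    ax.scatter(x[~flag], y[~flag], s=6, c="#4878cf", lw=0)
    if flag.any():
        ax.scatter(x[flag], y[flag], s=8, c="#d65f5f", lw=0)
    ax.axvline(0, color="k", lw=0.8)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xlabel("top-5% non-neighbor sim - best neighbor sim")
    ax.set_ylabel("top-5% non-neighbor sim - median neighbor sim")
    ax.set_title(f"High-Similarity Non-Neighbor (pass {report.hsnn_pass_frac:.1%})",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, **_SAVE)
    plt.close(fig)
    return Path(out_path)


def plot_concordance(report, out_path) -> Path:
    """Pairwise image-distance (X) vs gene-distance (Y) scatter."""
    if report.concordance_pairs is None:
        raise ValueError("report has no concordance pairs (image modality absent)")
    dg, dm = report.concordance_pairs.T
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(dm, dg, s=4, c="#4878cf", alpha=0.4, lw=0)
    ax.set_xlabel("image-modality pair distance")
    ax.set_ylabel("gene-modality pair distance")
    ax.set_title(f"Modality Concordance (discordant {report.discordant_frac:.1%})",
                 fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, **_SAVE)
    plt.close(fig)
    return Path(out_path)


def plot_cluster_map(coords, labels, out_path, title: str = "clusters") -> Path:
    """Spatial map of spots colored by cluster label (tab20 palette)."""
    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    cmap = plt.get_cmap("tab20")
    for c in np.unique(labels):
        m = labels == c
        ax.scatter(coords[m, 0], coords[m, 1], s=10, color=cmap(int(c) % 20), lw=0)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: origin top-left
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(out_path, **_SAVE)
    plt.close(fig)
    return Path(out_path)


PLOT_KINDS = {
    "avg": plot_avg_similarity,
    "hsnn": plot_hsnn,
    "concordance": plot_concordance,
    "clusters": plot_cluster_map,
}
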