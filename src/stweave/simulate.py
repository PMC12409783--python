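"""Ground-truth multi-modal ST simulator.

Spots live on a regular lattice.  k cluster centers are placed on a
jittered near-square sub-lattice; true labels come either from the
nearest center ("distinct" pattern: spatially exclusive territories) or
are sampled from a distance-based softmax ("ambiguous" pattern: noisy,
interleaved territories whose bandwidth tau controls how often a spot's
label disagrees with its location; tau="auto" calibrates the expected
nearest-center agreement to 80%).

Modality confounding: the k true clusters are merged pairwise into k/2
gene groups ((0,1)(2,3)...) and a shifted pairing of k/2 image groups
((1,2)(3,4)...(k-1,0)), so neither modality alone can resolve all
clusters but the pair of group labels identifies each cluster uniquely.
Each modality is drawn from an isotropic Gaussian mixture: group means
carry ``effect`` on a disjoint block of ``markers_per_group`` marker
features and 0 elsewhere.  Entry-wise Bernoulli dropout (rate d) is
applied to expression only, mimicking sparse transcript capture; the
image modality is never dropped.

``render_synthetic_slide`` paints a toy slide where each spot's patch
area is colored by its image group, closing the loop for the image
featurization pathway.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass, field, asdict

import numpy as np

from .core_data import SpatialDataset
from .utils import derive_seed


@dataclass
class SimConfig:
    grid: tuple[int, int] = (30, 30)
    k: int = 10
    pattern: str = "distinct"
    dropout: float = 0.0
    tau: float | str = "auto"
    n_genes: int = 200
    n_imgfeat: int = 100
    effect: float = 1.0
    noise: float = 1.0
    markers_per_group: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pattern not in ("distinct", "ambiguous"):
            raise ValueError("pattern must be 'distinct' or 'ambiguous'")
        if self.effect <= 0 or self.noise <= 0:
            raise ValueError("effect and noise must be positive")


@dataclass
class SimResult:
    dataset: SpatialDataset
    gene_groups: np.ndarray
    image_groups: np.ndarray
    centers: np.ndarray
    config: SimConfig
    tau_used: float | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.dataset.labels

    def config_echo(self) -> dict:
        out = asdict(self.config)
        out["tau_used"] = self.tau_used
        return out


def grid_coords(grid: tuple[int, int]) -> np.ndarray:
    rows, cols = grid
    yy, xx = np.mgrid[0:rows, 0:cols]
    return np.column_stack([xx.ravel(), yy.ravel()]).astype(float)


def place_centers(k: int, grid: tuple[int, int] = (30, 30), seed: int = 0) -> np.ndarray:
    """Centers on a jittered near-square sub-lattice spanning the grid.

    rows_c = floor(sqrt(k)) lattice rows, cols_c = ceil(k / rows_c)
    columns; cells are filled row-major and the first k kept; jitter is
    uniform within +/-5% of the cell spacing.  Deterministic per seed.
    """
    rows, cols = grid
    if k > rows * cols:
        raise ValueError("more centers than grid cells")
    rng = np.random.default_rng(seed)
    rc = max(1, int(np.floor(np.sqrt(k))))
    cc = int(np.ceil(k / rc))
    cy = (np.arange(rc) + 0.5) * rows / rc
    cx = (np.arange(cc) + 0.5) * cols / cc
    centers = np.array([(x, y) for y in cy for x in cx])[:k]
    jitter = rng.uniform(-0.05, 0.05, centers.shape) * np.array([cols / cc, rows / rc])
    return centers + jitter


def assign_labels_distinct(coords: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Nearest-center assignment, ties to the lower center index."""
    if len(centers) < 1:
        raise ValueError("need at least one center")
    D = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
    return D.argmin(axis=1)


def _softmax_probs(coords: np.ndarray, centers: np.ndarray, tau: float) -> np.ndarray:
    D2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    L = -D2 / (2.0 * tau * tau)
    L -= L.max(axis=1, keepdims=True)
    P = np.exp(L)
    return P / P.sum(axis=1, keepdims=True)


def calibrate_tau(coords: np.ndarray, centers: np.ndarray,
                  target_agreement: float = 0.80, tol: float = 0.005) -> float:
    """Bisect tau so the expected nearest-center agreement of the softmax
    assignment equals ``target_agreement``.

    The expected agreement mean_i P_i(argmin_i) is monotone decreasing
    in tau (1 as tau -> 0, 1/k as tau -> infinity), so bisection over a
    bracket is exact up to ``tol``; no sampling involved.
    """
    nearest = assign_labels_distinct(coords, centers)
    idx = np.arange(coords.shape[0])

    def agreement(tau):
        return float(_softmax_probs(coords, centers, tau)[idx, nearest].mean())

    lo, hi = 1e-3, 1e3
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if agreement(mid) > target_agreement:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-6:
            break
    tau = np.sqrt(lo * hi)
    if abs(agreement(tau) - target_agreement) > tol:
        raise RuntimeError("tau calibration failed to converge")
    return float(tau)


def assign_labels_ambiguous(coords: np.ndarray, centers: np.ndarray,
                            tau: float | str = "auto", seed: int = 0):
    """Sample labels from P(label=j) proportional to exp(-d_j^2/(2 tau^2)).

    Returns (labels, tau used).  tau="auto" calibrates the expected
    agreement with the distinct assignment to 0.80.
    """
    if tau == "auto":
        tau = calibrate_tau(coords, centers)
    if tau <= 0:
        raise ValueError("tau must be positive")
    P = _softmax_probs(coords, centers, float(tau))
    rng = np.random.default_rng(seed)
    u = rng.random(coords.shape[0])
    labels = (u[:, None] > P.cumsum(axis=1)).sum(axis=1)
    return labels, float(tau)


def confound_map(k: int):
    """Pairwise modality merge maps for even k.

    gene map merges true clusters (0,1)(2,3)...; image map merges
    (1,2)(3,4)...(k-1,0).  The joint (gene group, image group) code is
    injective on the k clusters.
    """
    if k % 2:
        raise ValueError(f"confound_map requires an even cluster count, got k={k}")
    clusters = np.arange(k)
    gene_map = clusters // 2
    image_map = ((clusters + 1) % k) // 2
    return gene_map, image_map


def sample_modality(groups: np.ndarray, n_feat: int, effect: float = 1.0,
                    noise: float = 1.0, markers_per_group: int = 20,
                    seed: int = 0) -> np.ndarray:
    """Isotropic Gaussian-mixture features with disjoint marker blocks.

    Spot i ~ N(m_{g(i)}, noise^2 I); m_g has value ``effect`` on group
    g's block of ``markers_per_group`` features and 0 elsewhere.
    """
    groups = np.asarray(groups, dtype=int)
    n_groups = int(groups.max()) + 1
    if markers_per_group * n_groups > n_feat:
        raise ValueError(
            f"{n_groups} groups x {markers_per_group} markers exceed {n_feat} features"
        )
    means = np.zeros((n_groups, n_feat))
    for g in range(n_groups):
        means[g, g * markers_per_group:(g + 1) * markers_per_group] = effect
    rng = np.random.default_rng(seed)
    return means[groups] + rng.normal(0.0, noise, (groups.size, n_feat))


def apply_dropout(matrix: np.ndarray, d: float, seed: int = 0) -> np.ndarray:
    """Set each entry to 0 independently with probability d."""
    if not 0.0 <= d < 1.0:
        raise ValueError("dropout must lie in [0, 1)")
    if d == 0.0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    return np.where(rng.random(matrix.shape) < d, 0.0, matrix)


def simulate(config: SimConfig) -> SimResult:
    """Generate a full multi-modal simulated dataset with ground truth."""
    coords = grid_coords(config.grid)
    centers = place_centers(config.k, config.grid, derive_seed(config.seed, "centers"))
    tau_used = None
    if config.pattern == "distinct":
        labels = assign_labels_distinct(coords, centers)
    else:
        labels, tau_used = assign_labels_ambiguous(
            coords, centers, config.tau, derive_seed(config.seed, "labels"))
    gene_map, image_map = confound_map(config.k)
    gene_groups = gene_map[labels]
    image_groups = image_map[labels]
    expr = sample_modality(gene_groups, config.n_genes, config.effect, config.noise,
                           config.markers_per_group, derive_seed(config.seed, "gene"))
    expr = apply_dropout(expr, config.dropout, derive_seed(config.seed, "dropout"))
    imgf = sample_modality(image_groups, config.n_imgfeat, config.effect, config.noise,
                           config.markers_per_group, derive_seed(config.seed, "image"))
    dataset = SpatialDataset(
        spot_ids=[f"spot{i:04d}" for i in range(coords.shape[0])],
        coords=coords,
        expression=expr,
        image_features=imgf,
        labels=labels,
        meta={"pattern": config.pattern, "k": str(config.k),
              "dropout": str(config.dropout)},
    )
    return SimResult(dataset=dataset, gene_groups=gene_groups,
                     image_groups=image_groups, centers=centers,
                     config=config, tau_used=tau_used)


def _group_palette(n_groups: int) -> np.ndarray:
    # evenly spaced hues at fixed saturation/value; deterministic
    return np.array([colorsys.hsv_to_rgb(g / n_groups, 0.55, 0.9)
                     for g in range(n_groups)])


def render_synthetic_slide(result: SimResult, patch_size: int = 16,
                           color_noise: float = 0.05, seed: int = 0):
    """Paint a toy slide: each spot's patch area gets its image group's
    color plus Gaussian pixel noise, clipped to [0, 1].

    Returns (H x W x 3 image, n x 2 pixel coords of the spot centers);
    H = rows * patch_size, W = cols * patch_size.
    """
    rows, cols = result.config.grid
    p = int(patch_size)
    coords = result.dataset.coords.astype(int)
    palette = _group_palette(int(result.image_groups.max()) + 1)
    img = np.ones((rows * p, cols * p, 3))
    for (x, y), g in zip(coords, result.image_groups):
        img[y * p:(y + 1) * p, x * p:(x + 1) * p] = palette[g]
    if color_noise > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, color_noise, img.shape)
    img = np.clip(img, 0.0, 1.0)
    pixel_coords = coords * p + p // 2
    return img, pixel_coords.astype(float)
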