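"""Histology patch extraction and per-patch feature vectors.

The slide is partitioned into per-spot square patches centered on the
spot coordinates.  The default featurization is the RGB profile
(per-channel mean, standard deviation, and a normalized intensity
histogram): deterministic, download-free, and sufficient to separate
tissue morphologies that differ in stain color and texture intensity.
A pretrained-CNN backend (VGG16/ResNet50 penultimate pooled layer) is
pluggable for users with torch installed; a tiny seeded random-weight
network is provided for tests of the CNN contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .utils import check_finite


@dataclass
class PatchStack:
    """n patches of shape p x p x 3 with values in [0, 1], plus centers."""

    patches: np.ndarray
    patch_size: int
    centers: np.ndarray

    def __post_init__(self):
        self.patches = check_finite("patches", self.patches)
        p = self.patch_size
        if self.patches.ndim != 4 or self.patches.shape[1:] != (p, p, 3):
            raise ValueError(f"patches must be n x {p} x {p} x 3")
        if self.patches.min() < 0 or self.patches.max() > 1:
            raise ValueError("patch values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.patches.shape[0]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF image to an H x W x 3 float array in [0, 1]."""
    from PIL import Image

    with Image.open(Path(path)) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return arr


def extract_patches(image: np.ndarray, coords: np.ndarray, patch_size: int = 64) -> PatchStack:
    """Cut the per-spot patch stack out of the slide.

    Patch i is the half-open window [y - p/2, y + p/2) x [x - p/2, x + p/2)
    centered at spot i (floor convention; p must be even).  Out-of-bounds
    pixels are padded with white, matching H&E background.  Spots whose
    window lies entirely outside the image are fatal.
    """
    image = np.asarray(image, dtype=float)
    if image.dtype.kind != "f" or image.max() > 1.0:
        image = image / 255.0
    image = np.clip(image, 0.0, 1.0)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be H x W x 3")
    H, W, _ = image.shape
    p = int(patch_size)
    if p <= 0 or p % 2:
        raise ValueError("patch_size must be an even positive integer")
    if p > min(H, W):
        raise ValueError(f"patch_size {p} exceeds image dimensions {H}x{W}")
    coords = check_finite("coords", coords)
    half = p // 2
    n = coords.shape[0]
    out = np.ones((n, p, p, 3), dtype=float)  # white padding
    offenders = []
    for i, (x, y) in enumerate(coords):
        cx, cy = int(np.floor(x)), int(np.floor(y))
        y0, y1 = cy - half, cy + half
        x0, x1 = cx - half, cx + half
        if y1 <= 0 or x1 <= 0 or y0 >= H or x0 >= W:
            offenders.append(i)
            continue
        sy0, sy1 = max(y0, 0), min(y1, H)
        sx0, sx1 = max(x0, 0), min(x1, W)
        out[i, sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = image[sy0:sy1, sx0:sx1]
    if offenders:
        raise ValueError(f"spots entirely outside the image: {offenders}")
    return PatchStack(patches=out, patch_size=p, centers=np.asarray(coords, dtype=float))


def rgb_features(patches: PatchStack, hist_bins: int = 8) -> np.ndarray:
    """RGB-profile features: per-channel mean, sd, and normalized histogram.

    F = 3 * (2 + hist_bins); histogram rows sum to 1 per channel.  The
    features are invariant to within-patch pixel permutation.
    """
    if hist_bins < 1:
        raise ValueError("hist_bins must be >= 1")
    P = patches.patches
    n, p = patches.n, patches.patch_size
    flat = P.reshape(n, p * p, 3)
    means = flat.mean(axis=1)
    sds = flat.std(axis=1)
    hists = np.empty((n, 3, hist_bins))
    edges = np.linspace(0.0, 1.0, hist_bins + 1)
    for c in range(3):
        for i in range(n):
            h, _ = np.histogram(flat[i, :, c], bins=edges)
            hists[i, c] = h / (p * p)
    return np.hstack([means, sds, hists.reshape(n, 3 * hist_bins)])


def _tiny_random_net(patches: np.ndarray, seed: int) -> np.ndarray:
    """A small fixed-architecture random-weight convnet (numpy).

    Two strided 3x3 convolutions with ReLU, then global average pooling:
    3 -> 8 -> 16 channels, 16 output features.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    W1 = rng.normal(0, 0.3, (8, 3, 3, 3))
    W2 = rng.normal(0, 0.3, (16, 8, 3, 3))

    def conv(x, W, stride=2):
        n, h, w, cin = x.shape
        cout, _, kh, kw = W.shape
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        out = np.zeros((n, oh, ow, cout))
        for a in range(kh):
            for b in range(kw):
                sub = x[:, a:a + stride * oh:stride, b:b + stride * ow:stride, :]
                out += np.einsum("nhwc,oc->nhwo", sub, W[:, :, a, b])
        return np.maximum(out, 0.0)

    h = conv(patches, W1)
    h = conv(h, W2)
    return h.mean(axis=(1, 2))


def cnn_features(patches: PatchStack, backend: str = "tiny-random",
                 seed: int = 0, layer: str | None = None) -> np.ndarray:
    """CNN patch features: one row per patch, deterministic per seed.

    ``tiny-random`` is a seeded random-weight network for testing the
    contract without downloads.  ``vgg16``/``resnet50`` use ImageNet
    pretrained weights via torchvision (penultimate pooled layer by
    default) and require the optional ``cnn`` extra.
    """
    if backend == "tiny-random":
        return _tiny_random_net(patches.patches, seed)
    if backend in ("vgg16", "resnet50"):
        try:
            import torch
            import torchvision.models as models
        except ImportError as exc:
            raise ImportError(
                f"backend {backend!r} needs torch/torchvision (install the "
                "'cnn' extra); the 'rgb' featurizer (rgb_features) works "
                "without downloads"
            ) from exc
        torch.manual_seed(seed)
        net = (models.vgg16(weights="IMAGENET1K_V1") if backend == "vgg16"
               else models.resnet50(weights="IMAGENET1K_V1"))
        net.eval()
        x = torch.tensor(patches.patches.transpose(0, 3, 1, 2), dtype=torch.float32)
        mean = torch.tensor([0.485, 0.456, 0.406]).view(1, 3, 1, 1)
        std = torch.tensor([0.229, 0.224, 0.225]).view(1, 3, 1, 1)
        x = (x - mean) / std
        with torch.no_grad():
            if backend == "vgg16":
                feats = net.avgpool(net.features(x)).flatten(1)
            else:
                body = torch.nn.Sequential(*list(net.children())[:-1])
                feats = body(x).flatten(1)
        return feats.numpy()
    raise ValueError(f"unknown backend {backend!r}; use rgb_features or tiny-random")
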