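"""MRI-sequence encoder: residual 3-D CNN embeddings trained with a
fixed-anchor triplet margin loss, plus augmentation and Grad-CAM saliency.

Each MRI sequence (T1-pre, T1-post, T2, FLAIR, PD) has its own independent
channel.  A channel maps a skull-stripped, registered volume of arbitrary
extents to a fixed-length embedding (global average pooling precedes the
head, so the embedding length is input-size independent).  Channels are
metric-trained: with the anchor ``a`` fixed in embedding space (the origin by
default),

    loss = sum_i max(d(a, p_i) - d(a, n_i) + margin, 0),   d = Euclidean,

pulls milestone-positive patients toward the anchor and pushes negatives
beyond the margin (default 1.5).  Training defaults: learning rate 1e-5,
batch 10, up to 500 epochs, early stop after 50 non-improving epochs.

Saliency uses gradient-weighted class activation mapping on the last
convolutional layer: the prediction target is the embedding's distance to
the anchor, channel weights are its spatially averaged gradient magnitudes
(the metric head makes per-channel gradient signs arbitrary), and the
weighted activation sum is rectified and upsampled to the input grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .autodiff import Conv3d, Linear, Module, Tensor

__all__ = [
    "ImageEncoderConfig",
    "ResidualVolumeEncoder",
    "triplet_margin_loss",
    "augment",
    "select_scan",
    "saliency",
]


@dataclass
class ImageEncoderConfig:
    width: int = 4                 # stem channels; doubled at the second stage
    n_res_blocks: int = 1
    embedding_dim: int = 16
    margin: float = 1.5
    anchor: np.ndarray | None = None   # default: origin of the embedding space
    learning_rate: float = 1e-5
    batch_size: int = 10
    epochs: int = 500
    patience: int = 50

    def anchor_point(self) -> np.ndarray:
        if self.anchor is None:
            return np.zeros(self.embedding_dim)
        return np.asarray(self.anchor, dtype=float)


class _ResBlock(Module):
    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(channels, channels, 3, rng, stride=1, padding=1)
        self.conv2 = Conv3d(channels, channels, 3, rng, stride=1, padding=1)

    def forward(self, x: Tensor) -> Tensor:
        return (self.conv2(self.conv1(x).relu()) + x).relu()


class ResidualVolumeEncoder(Module):
    """Small residual 3-D CNN with global average pooling and a linear head."""

    def __init__(self, cfg: ImageEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        w = cfg.width
        self.stem = Conv3d(1, w, 3, rng, stride=2, padding=1)
        self.blocks = [_ResBlock(w, rng) for _ in range(cfg.n_res_blocks)]
        self.down = Conv3d(w, 2 * w, 3, rng, stride=2, padding=1)
        self.blocks2 = [_ResBlock(2 * w, rng) for _ in range(cfg.n_res_blocks)]
        self.head = Linear(2 * w, cfg.embedding_dim, rng)
        self._last_conv_activations: Tensor | None = None

    def features(self, x: Tensor) -> Tensor:
        """Last convolutional feature map, shape (B, C, x', y', z')."""
        h = self.stem(x).relu()
        for b in self.blocks:
            h = b(h)
        h = self.down(h).relu()
        for b in self.blocks2:
            h = b(h)
        self._last_conv_activations = h
        return h

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """Embed a batch of volumes (B, X, Y, Z) -> (B, embedding_dim)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim == 3:
            x = x.reshape(1, *x.shape)
        b = x.shape[0]
        h = self.features(x.reshape(b, 1, *x.shape[1:]))
        pooled = h.mean(axis=(2, 3, 4))  # global average pool
        return self.head(pooled)

    def embed(self, volume: np.ndarray) -> np.ndarray:
        """Deterministic single-volume embedding (eval mode)."""
        self.eval()
        if not np.all(np.isfinite(volume)):
            raise ValueError("volume intensities must be finite")
        return self(normalize_intensity(volume))[0].numpy()


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Min-max intensity normalization to [0, 1]; constant volumes map to 0."""
    volume = np.asarray(volume, dtype=float)
    lo, hi = volume.min(), volume.max()
    if hi == lo:
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo)


def triplet_margin_loss(anchor: np.ndarray | Tensor,
                        positives: Tensor | np.ndarray,
                        negatives: Tensor | np.ndarray,
                        margin: float = 1.5) -> Tensor:
    """``sum_i max(d(a, p_i) - d(a, n_i) + margin, 0)`` with Euclidean d.

    ``positives`` and ``negatives`` are (m, dim) batches sharing the anchor's
    dimensionality; reduction is the sum over batch items, following the
    printed hinge formula.
    """
    if margin <= 0:
        raise ValueError("margin must be positive")
    a = anchor if isinstance(anchor, Tensor) else Tensor(np.asarray(anchor, dtype=float))
    p = positives if isinstance(positives, Tensor) else Tensor(positives)
    n = negatives if isinstance(negatives, Tensor) else Tensor(negatives)
    if p.shape[0] == 0:
        raise ValueError("triplet batch must be non-empty")
    if p.shape[-1] != a.shape[-1] or n.shape[-1] != a.shape[-1]:
        raise ValueError(
            f"embedding dims differ: anchor {a.shape[-1]}, "
            f"positives {p.shape[-1]}, negatives {n.shape[-1]}"
        )
    eps = 1e-12  # keeps sqrt differentiable at zero distance
    d_p = (((p - a) ** 2).sum(axis=-1) + eps).sqrt()
    d_n = (((n - a) ** 2).sum(axis=-1) + eps).sqrt()
    return (d_p - d_n + margin).maximum(0.0).sum()


def augment(volume: np.ndarray, rng: np.random.Generator,
            mode: str = "train") -> np.ndarray:
    """Training-time augmentation; ``mode='eval'`` is the identity.

    Applies intensity normalization, then horizontal and vertical flips each
    with probability 0.5, a rotation with probability 0.5 by per-axis angles
    uniform in [-0.02, +0.02] degrees, and a random zoom-out followed by a
    resize back to the original extents.
    """
    if mode == "eval":
        return volume
    vol = normalize_intensity(volume)
    if rng.random() < 0.5:
        vol = vol[::-1, :, :].copy()       # horizontal flip
    if rng.random() < 0.5:
        vol = vol[:, ::-1, :].copy()       # vertical flip
    if rng.random() < 0.5:
        for axes in ((0, 1), (0, 2), (1, 2)):
            angle = rng.uniform(-0.02, 0.02)
            vol = ndimage.rotate(vol, angle, axes=axes, reshape=False,
                                 order=1, mode="nearest")
    factor = rng.uniform(0.8, 1.0)         # zoom-out then resize
    if factor < 1.0:
        small = ndimage.zoom(vol, factor, order=1)
        vol = ndimage.zoom(small, [o / s for o, s in zip(vol.shape, small.shape)],
                           order=1)
    return np.clip(vol, 0.0, 1.0)


def select_scan(sessions: list[dict]) -> dict | None:
    """The chronologically last scan session (most recent disease status);
    ``None`` when the patient has no imaging (zero embeddings downstream)."""
    if not sessions:
        return None
    return max(sessions, key=lambda s: s["time"])


def saliency(model: ResidualVolumeEncoder, volume: np.ndarray) -> np.ndarray:
    """Grad-CAM map over the input grid, nonnegative.

    The prediction target is the distance of the embedding to the configured
    anchor — the quantity the metric objective separates classes by.  Under
    a metric (rather than classification) head the gradient's sign is an
    arbitrary consequence of initialization, so channel weights are the
    spatially averaged gradient *magnitudes*; the weighted activation sum is
    rectified and upsampled to the input grid.
    """
    model.eval()
    x = Tensor(normalize_intensity(volume))
    emb = model(x)  # records last conv activations
    acts = model._last_conv_activations
    if acts is None:
        raise ValueError("model has no convolutional layers to attribute to")
    a = Tensor(model.cfg.anchor_point())
    target = (((emb[0] - a) ** 2).sum() + 1e-12).sqrt()
    target.backward()
    grads = acts.grad[0]                            # (C, x', y', z')
    weights = np.abs(grads).mean(axis=(1, 2, 3))    # channel sensitivities
    cam = np.einsum("c,cxyz->xyz", weights, acts.data[0])
    cam = np.maximum(cam, 0.0)
    zoom = [o / s for o, s in zip(volume.shape, cam.shape)]
    return np.maximum(ndimage.zoom(cam, zoom, order=1), 0.0)
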