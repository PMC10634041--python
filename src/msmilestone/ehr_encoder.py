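"""Structured-EHR encoder channels: temporal attention by stacked 1-D CNNs.

Each binned table ``D_k`` (t_k time bins x f_k features) is pooled to a
fixed-length embedding ``e_k = alpha_k^T D_k`` of length ``f_k``.  The
attention weight of a bin is produced by running that bin's feature vector
through a stack of 1-D convolutions over the feature axis (ReLU + dropout
between layers), average-pooling the final single-channel output to one
scalar, and normalizing the t_k scalars with a softmax over time.  Because
the weights are computed row-locally, permuting the rows of ``D_k`` leaves
``e_k`` unchanged, and with normalized weights every coordinate of ``e_k``
is a convex combination of the corresponding feature column.

Default channel geometries (per table kind):

========== ==========================================
lab        1->8 k7 s2, 8->8 k4 s2, 8->1 k3 s2
vital      1->8 k3 s2, 8->1 k2 s2
medication 1->8 k3 s2, 8->1 k2 s2
========== ==========================================

with dropout 0.3 after every convolution and average pooling at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Conv1d, Dropout, Module, Tensor, softmax
from .preprocess import LongitudinalTable

__all__ = [
    "ConvLayerSpec",
    "ChannelConfig",
    "default_channel_config",
    "EHRChannel",
    "compute_attention_weights",
    "embed_table",
]


@dataclass
class ConvLayerSpec:
    in_channels: int
    out_channels: int
    kernel: int
    stride: int
    padding: int | str = "same"


@dataclass
class ChannelConfig:
    layers: list[ConvLayerSpec]
    dropout: float = 0.3
    pooling: str = "avg"
    normalize: str = "softmax"   # 'softmax' or 'raw' attention weights

    def __post_init__(self):
        if not self.layers:
            raise ValueError("channel needs at least one conv layer")
        if self.layers[-1].out_channels != 1:
            raise ValueError("last conv layer must have a single output channel")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


_DEFAULTS = {
    "lab": [(1, 8, 7, 2), (8, 8, 4, 2), (8, 1, 3, 2)],
    "vital": [(1, 8, 3, 2), (8, 1, 2, 2)],
    "medication": [(1, 8, 3, 2), (8, 1, 2, 2)],
}


def default_channel_config(kind: str) -> ChannelConfig:
    """Per-kind default geometry; unknown kinds fall back to the vital config."""
    spec = _DEFAULTS.get(kind, _DEFAULTS["vital"])
    return ChannelConfig(layers=[ConvLayerSpec(*s) for s in spec])


class EHRChannel(Module):
    """One table kind's attention channel."""

    def __init__(self, cfg: ChannelConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.convs = [
            Conv1d(s.in_channels, s.out_channels, s.kernel, rng,
                   stride=s.stride, padding=s.padding)
            for s in cfg.layers
        ]
        self.dropouts = [Dropout(cfg.dropout, rng=np.random.default_rng(rng.integers(2**31)))
                         for _ in cfg.layers]

    def attention(self, table: Tensor | np.ndarray) -> Tensor:
        """Per-bin attention weights for a (t_k, f_k) table, as a length-t_k
        tensor (normalized per the config)."""
        x = table if isinstance(table, Tensor) else Tensor(table)
        t_k, f_k = x.shape
        if t_k == 0:
            raise ValueError("empty table: caller should substitute the zero embedding")
        h = x.reshape(t_k, 1, f_k)  # rows as batch, features as length
        for i, (conv, drop) in enumerate(zip(self.convs, self.dropouts)):
            h = conv(h)
            if i > 0:
                h = h.relu()
            h = drop(h)
        if self.cfg.pooling != "avg":
            raise ValueError(f"unsupported pooling {self.cfg.pooling!r}")
        scores = h.mean(axis=2).reshape(t_k)  # single channel -> scalar per row
        if self.cfg.normalize == "softmax":
            return softmax(scores, axis=0)
        return scores

    def forward(self, table: Tensor | np.ndarray) -> Tensor:
        """Embedding ``e_k = alpha_k^T D_k`` (length f_k)."""
        x = table if isinstance(table, Tensor) else Tensor(table)
        if x.shape[0] == 0:
            return Tensor(np.zeros(x.shape[1]))
        alpha = self.attention(x)
        return alpha @ x


def compute_attention_weights(table: LongitudinalTable | np.ndarray,
                              channel: EHRChannel,
                              mode: str = "eval") -> np.ndarray:
    """Functional wrapper: attention weights of a table under a channel."""
    values = table.values if isinstance(table, LongitudinalTable) else np.asarray(table)
    if values.shape[0] == 0:
        return np.zeros(0)
    channel.eval() if mode == "eval" else channel.train()
    return channel.attention(values).numpy()


def embed_table(table: LongitudinalTable | np.ndarray,
                alpha: np.ndarray) -> np.ndarray:
    """``e_k = alpha^T D_k``; an empty table yields the all-zero vector."""
    values = table.values if isinstance(table, LongitudinalTable) else np.asarray(table)
    alpha = np.asarray(alpha, dtype=float)
    if values.shape[0] == 0:
        return np.zeros(values.shape[1])
    if alpha.shape[0] != values.shape[0]:
        raise ValueError(
            f"attention length {alpha.shape[0]} != table rows {values.shape[0]}"
        )
    return alpha @ values
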