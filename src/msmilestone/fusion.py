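"""Multimodal fusion and the recurrent attention decoder.

The per-modality embeddings are stacked into a causally ordered matrix
``E`` (K x d): observations first (vital signs, laboratory tests), then the
five MRI sequences, the clinical note (the "diagnosis" slot), and finally
medications.  Shorter embeddings are right-padded with zeros to
``d = max(f_1, ..., f_K)``; a missing modality contributes an all-zero row.

The decoder runs a stacked bidirectional GRU over the K rows (sequence
length K, input size d; hidden states ``C`` of width ``h = 2 x hidden``),
computes per-state attention vectors ``gamma_k`` of length g with a 1-D
convolution over the state axis (stacked into ``B``, K x g), forms
``O = B^T C`` (g x h), and maps ``Flatten(O)`` concatenated with the
demographics vector through a fully connected head to the milestone
probability ``o = sigmoid(FC(...)) in [0, 1]``.

Paper-scale defaults are 4 GRU layers with hidden size 512; g is a free
hyperparameter (default 8).  Training of this stage uses binary
cross-entropy on the milestone label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import GRU, Conv1d, Linear, Module, Tensor, concat

__all__ = [
    "DEFAULT_ROW_ORDER",
    "FusionMatrix",
    "build_fusion_matrix",
    "DecoderConfig",
    "FusionDecoder",
    "bce_loss",
]

#: Causal ordering: observations -> imaging -> note (diagnosis slot) -> meds.
DEFAULT_ROW_ORDER = (
    "vital", "lab", "t1_pre", "t1_post", "t2", "flair", "pd", "note", "medication",
)


@dataclass
class FusionMatrix:
    values: np.ndarray           # (K, d)
    row_order: tuple[str, ...]

    @property
    def K(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


def build_fusion_matrix(embeddings: dict[str, np.ndarray | None],
                        row_order: tuple[str, ...] = DEFAULT_ROW_ORDER,
                        d: int | None = None) -> FusionMatrix:
    """Stack modality embeddings into the zero-padded K x d matrix ``E``.

    ``embeddings`` maps modality name to a 1-D vector or ``None`` (missing).
    ``d`` fixes the padded width; by default it is the maximum embedding
    length present.  All modalities missing is an error.
    """
    vectors = {k: embeddings.get(k) for k in row_order}
    present = [v for v in vectors.values() if v is not None and np.asarray(v).size > 0]
    if not present:
        raise ValueError("all modalities missing: cannot build a fusion matrix")
    if d is None:
        d = max(np.asarray(v).shape[0] for v in present)
    e = np.zeros((len(row_order), d))
    for i, name in enumerate(row_order):
        v = vectors[name]
        if v is None:
            continue
        v = np.asarray(v, dtype=float).ravel()
        if v.shape[0] > d:
            raise ValueError(
                f"embedding for {name!r} has length {v.shape[0]} > padded width {d}"
            )
        e[i, : v.shape[0]] = v
    return FusionMatrix(values=e, row_order=tuple(row_order))


@dataclass
class DecoderConfig:
    input_size: int                  # d, the padded embedding width
    demographics_dim: int
    hidden: int = 512
    layers: int = 4
    attention_channels: int = 8      # g
    attention_kernel: int = 3
    row_order: tuple[str, ...] = DEFAULT_ROW_ORDER


class FusionDecoder(Module):
    """Bi-GRU over the fusion rows with convolutional attention and FC head."""

    def __init__(self, cfg: DecoderConfig, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.gru = GRU(cfg.input_size, cfg.hidden, rng, num_layers=cfg.layers,
                       bidirectional=True)
        self.h = 2 * cfg.hidden
        self.att_conv = Conv1d(1, cfg.attention_channels, cfg.attention_kernel,
                               rng, stride=1, padding="same")
        self.fc = Linear(cfg.attention_channels * self.h + cfg.demographics_dim,
                         1, rng)

    def states(self, e_batch: Tensor) -> Tensor:
        """Bi-GRU hidden states C, shape (B, K, h)."""
        return self.gru(e_batch)

    def attention_matrix(self, c: Tensor) -> Tensor:
        """Per-state attention vectors gamma_k stacked into B, (batch, K, g)."""
        b, k, h = c.shape
        conv_in = c.reshape(b * k, 1, h)
        conv_out = self.att_conv(conv_in)            # (b*k, g, h)
        gamma = conv_out.mean(axis=2)                # pool over the state axis
        return gamma.reshape(b, k, self.cfg.attention_channels)

    def forward(self, e_batch: Tensor | np.ndarray,
                dem_batch: Tensor | np.ndarray) -> Tensor:
        """Milestone probabilities for a batch: (B, K, d), (B, dem) -> (B,)."""
        e = e_batch if isinstance(e_batch, Tensor) else Tensor(e_batch)
        dem = dem_batch if isinstance(dem_batch, Tensor) else Tensor(dem_batch)
        if e.ndim == 2:
            e = e.reshape(1, *e.shape)
        if dem.ndim == 1:
            dem = dem.reshape(1, -1)
        if e.shape[1] != len(self.cfg.row_order):
            raise ValueError(
                f"fusion matrix has {e.shape[1]} rows; decoder was built for "
                f"{len(self.cfg.row_order)}"
            )
        c = self.states(e)                           # (B, K, h)
        b_att = self.attention_matrix(c)             # (B, K, g)
        o_mat = b_att.transpose(0, 2, 1) @ c         # O = B^T C, (B, g, h)
        flat = o_mat.reshape(e.shape[0], -1)
        logits = self.fc(concat([flat, dem], axis=1)).reshape(e.shape[0])
        return logits.sigmoid()

    def predict(self, fusion: FusionMatrix, dem: np.ndarray) -> float:
        """Deterministic single-patient probability (eval mode)."""
        self.eval()
        return float(self(fusion.values, dem).numpy()[0])


def bce_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Binary cross-entropy on probabilities, mean over the batch."""
    y = Tensor(np.asarray(labels, dtype=float))
    eps = 1e-7
    p = probs * (1 - 2 * eps) + eps  # clamp away from {0, 1}
    one = Tensor(1.0)
    return -(y * p.log() + (one - y) * (one - p).log()).mean()
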