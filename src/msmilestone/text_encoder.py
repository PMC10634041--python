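"""Clinical-note encoder: graph message passing over a word co-occurrence
network with a document node and a self-attention readout.

A note is tokenized (lowercase, split on non-word characters) and turned into
a weighted directed graph: for every sliding window of ``window`` consecutive
tokens (stride 1) and every ordered pair of distinct-word positions within
it, the earlier->later edge weight is incremented; an extra document node is
connected to every word node with unit-weight edges in both directions.

Node states ``H`` (one row per node, width ``d_node``) start from a trainable
word-embedding table and are refined for ``T`` message-passing steps:

    M = MLP(D_deg^{-1} A H)          (out-degree row normalization)
    H' = GRU(H, M)                   (gated recurrent combine, per node)

The document vector is a softmax self-attention readout over the word nodes
only (document node removed):

    Y = tanh(H W_A),  beta_i = softmax(Y_i . v),  u = sum_i beta_i H_i

The channel is trained with the same fixed-anchor triplet margin loss as the
image channel.  Defaults: window 10, T = 2 passes, GRU hidden (= node width)
64, batch 128, learning rate 1e-3, 500 epochs with patience 50.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .autodiff import GRUCell, Linear, MLP, Module, Tensor, softmax

__all__ = [
    "WordGraph",
    "tokenize",
    "build_word_graph",
    "message_pass",
    "readout",
    "GraphNoteEncoder",
]

logger = logging.getLogger(__name__)

DOC_NODE = "<doc>"


@dataclass
class WordGraph:
    """Weighted directed co-occurrence graph plus a document node (last row)."""

    nodes: list[str]                # distinct words, document node last
    adjacency: np.ndarray           # (n, n) nonnegative weights, zero diagonal
    node_index: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def doc_index(self) -> int:
        return self.n - 1

    def degree_normalized_adjacency(self) -> np.ndarray:
        """``D_deg^{-1} A`` with out-degree row sums; isolated rows are zero."""
        deg = self.adjacency.sum(axis=1)
        inv = np.where(deg > 0, 1.0 / np.where(deg > 0, deg, 1.0), 0.0)
        return inv[:, None] * self.adjacency


def tokenize(text: str) -> list[str]:
    return [t for t in re.split(r"\W+", text.lower()) if t]


def build_word_graph(tokens: list[str], window: int = 10) -> WordGraph:
    """Sliding-window co-occurrence graph over a token sequence.

    Every ordered pair of positions (earlier -> later) inside each window
    contributes 1 to that directed edge; pairs of identical words are skipped
    (no self-loops).  Overlapping windows deliberately up-weight near pairs.
    """
    if not tokens:
        raise ValueError("cannot build a word graph from an empty token list")
    if window < 1:
        raise ValueError("window must be at least 1")
    words: list[str] = []
    index: dict[str, int] = {}
    for t in tokens:
        if t not in index:
            index[t] = len(words)
            words.append(t)
    n = len(words) + 1
    a = np.zeros((n, n))
    n_windows = max(len(tokens) - window + 1, 1)
    for start in range(n_windows):
        win = tokens[start : start + window]
        for i in range(len(win)):
            for j in range(i + 1, len(win)):
                if win[i] != win[j]:
                    a[index[win[i]], index[win[j]]] += 1.0
    doc = n - 1
    a[doc, :doc] = 1.0
    a[:doc, doc] = 1.0
    nodes = words + [DOC_NODE]
    return WordGraph(nodes=nodes, adjacency=a,
                     node_index={**index, DOC_NODE: doc})


def message_pass(h: Tensor | np.ndarray, graph: WordGraph, mlp, gru: GRUCell) -> Tensor:
    """One propagation step: ``H' = GRU(H, MLP(D_deg^{-1} A H))``.

    ``mlp`` may be any callable on tensors (the identity is useful for
    oracle checks); ``gru`` combines each node's state with its message.
    """
    h = h if isinstance(h, Tensor) else Tensor(h)
    if h.shape[0] != graph.n:
        raise ValueError(f"H has {h.shape[0]} rows but graph has {graph.n} nodes")
    m = Tensor(graph.degree_normalized_adjacency()) @ h
    m = mlp(m)
    return gru(m, h)


def readout(h_final: Tensor | np.ndarray, w_a: Tensor, v: Tensor,
            doc_index: int | None = None) -> tuple[Tensor, Tensor]:
    """Self-attention readout over word nodes (document node excluded).

    Returns ``(u, beta)`` where ``beta`` is a softmax over the n-1 word
    nodes and ``u`` the beta-weighted sum of their states.
    """
    h = h_final if isinstance(h_final, Tensor) else Tensor(h_final)
    n = h.shape[0]
    if n < 2:
        raise ValueError("readout needs at least one word node besides the document node")
    if doc_index is None:
        doc_index = n - 1
    keep = [i for i in range(n) if i != doc_index]
    h_words = h[keep]
    y = (h_words @ w_a).tanh()
    scores = y @ v
    beta = softmax(scores, axis=0)
    u = beta @ h_words
    return u, beta


class GraphNoteEncoder(Module):
    """Trainable document embedding channel.

    A shared word-embedding table initializes node states (the document node
    has its own trainable row); each of the ``T`` passes owns an MLP and a
    GRU combine; the readout projection/context are trained jointly.  An
    optional word2vec-text-format table can overwrite initial embeddings.
    """

    def __init__(self, vocab: list[str], rng: np.random.Generator,
                 d_node: int = 64, n_passes: int = 2, window: int = 10,
                 mlp_hidden: int | None = None):
        super().__init__()
        self.vocab = list(vocab)
        self.word_index = {w: i for i, w in enumerate(self.vocab)}
        self.window = window
        self.n_passes = n_passes
        self.d_node = d_node
        self.embeddings = Tensor(rng.normal(0, 0.1, size=(len(vocab) + 2, d_node)),
                                 requires_grad=True)  # + doc node + OOV rows
        hidden = mlp_hidden or d_node
        self.mlps = [MLP([d_node, hidden, d_node], rng) for _ in range(n_passes)]
        self.grus = [GRUCell(d_node, d_node, rng) for _ in range(n_passes)]
        self.w_a = Tensor(rng.normal(0, 0.1, size=(d_node, d_node)), requires_grad=True)
        self.v = Tensor(rng.normal(0, 0.1, size=d_node), requires_grad=True)

    @property
    def doc_row(self) -> int:
        return len(self.vocab)

    @property
    def oov_row(self) -> int:
        return len(self.vocab) + 1

    def load_word2vec(self, path) -> int:
        """Overwrite initial embeddings from a word2vec text-format file.
        Returns the number of vocabulary words found."""
        found = 0
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().split()
            dim = int(header[1]) if len(header) == 2 else None
            if dim is not None and dim != self.d_node:
                raise ValueError(f"embedding dim {dim} != d_node {self.d_node}")
            for line in fh:
                parts = line.rstrip().split(" ")
                w = parts[0]
                if w in self.word_index:
                    self.embeddings.data[self.word_index[w]] = np.asarray(
                        parts[1:], dtype=float)
                    found += 1
        return found

    def initial_states(self, graph: WordGraph) -> Tensor:
        rows = [self.word_index.get(w, self.oov_row) for w in graph.nodes[:-1]]
        rows.append(self.doc_row)
        return self.embeddings[rows]

    def embed_graph(self, graph: WordGraph) -> Tensor:
        h = self.initial_states(graph)
        for mlp, gru in zip(self.mlps, self.grus):
            h = message_pass(h, graph, mlp, gru)
        if graph.n < 2:
            return h[0]
        u, _ = readout(h, self.w_a, self.v, doc_index=graph.doc_index)
        return u

    def forward(self, text: str) -> Tensor:
        """Embed raw text; empty/garbage text yields the zero vector."""
        tokens = tokenize(text)
        if not tokens:
            logger.warning("note produced no tokens; emitting zero embedding")
            return Tensor(np.zeros(self.d_node))
        return self.embed_graph(build_word_graph(tokens, self.window))
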