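"""Word-graph construction, message passing and readout contracts."""

import numpy as np
import pytest

from msmilestone.autodiff import GRUCell, Tensor
from msmilestone.text_encoder import (DOC_NODE, GraphNoteEncoder, WordGraph,
                                      build_word_graph, message_pass, readout,
                                      tokenize)


class TestGraphConstruction:
    def test_two_token_note_single_directed_edge(self):
        g = build_word_graph(["a", "b"], window=2)
        assert g.nodes == ["a", "b", DOC_NODE]
        i, j, d = g.node_index["a"], g.node_index["b"], g.doc_index
        assert g.adjacency[i, j] == 1.0
        assert g.adjacency[j, i] == 0.0  # direction preserved
        # document node connected to every word node, both ways
        assert (g.adjacency[d, :d] == 1.0).all()
        assert (g.adjacency[:d, d] == 1.0).all()
        assert np.trace(g.adjacency) == 0.0

    def test_repeated_token_has_no_self_loops(self):
        g = build_word_graph(["x", "x", "x"], window=10)
        assert g.n == 2  # the word plus the document node
        assert g.adjacency[0, 0] == 0.0

    def test_twelve_token_sentence_matches_window_enumeration(self, rng):
        """Edge weights equal an explicit nested-loop enumeration of ordered
        pairs over every stride-1 window of size 3."""
        tokens = [f"w{i}" for i in rng.integers(0, 6, size=12)]
        window = 3
        g = build_word_graph(tokens, window=window)
        words = sorted(set(tokens), key=tokens.index)
        n = len(words) + 1
        expected = np.zeros((n, n))
        index = {w: i for i, w in enumerate(words)}
        for start in range(len(tokens) - window + 1):
            win = tokens[start : start + window]
            for i in range(window):
                for j in range(i + 1, window):
                    if win[i] != win[j]:
                        expected[index[win[i]], index[win[j]]] += 1
        expected[n - 1, : n - 1] = 1.0
        expected[: n - 1, n - 1] = 1.0
        np.testing.assert_array_equal(g.adjacency, expected)

    def test_short_note_uses_single_window(self):
        g = build_word_graph(["a", "b", "c"], window=10)
        assert g.adjacency[g.node_index["a"], g.node_index["c"]] == 1.0

    def test_empty_tokens_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_word_graph([], window=10)


class TestMessagePassing:
    def path_graph(self):
        # a -> b -> c word path plus the document node
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 2] = 1.0
        a[3, :3] = 1.0
        a[:3, 3] = 1.0
        return WordGraph(nodes=["a", "b", "c", DOC_NODE], adjacency=a,
                         node_index={"a": 0, "b": 1, "c": 2, DOC_NODE: 3})

    def test_identity_mlp_step_matches_per_node_loop(self, rng):
        """With the MLP fixed to the identity, one step gate-combines H with
        exact out-degree-normalized neighbor means."""
        g = self.path_graph()
        h = rng.normal(size=(4, 5))
        gru = GRUCell(5, 5, rng)
        out = message_pass(h, g, mlp=lambda t: t, gru=gru).numpy()

        # oracle: per-node aggregation loop, then the same GRU equations
        m = np.zeros_like(h)
        for v in range(4):
            w = g.adjacency[v]
            if w.sum() > 0:
                m[v] = (w[:, None] * h).sum(axis=0) / w.sum()
        def sigmoid(x):
            return 1 / (1 + np.exp(-x))
        gi = m @ gru.w_ih.data + gru.b_ih.data
        gh = h @ gru.w_hh.data + gru.b_hh.data
        r = sigmoid(gi[:, :5] + gh[:, :5])
        z = sigmoid(gi[:, 5:10] + gh[:, 5:10])
        nn = np.tanh(gi[:, 10:] + r * gh[:, 10:])
        expected = (1 - z) * nn + z * h
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_zero_states_biasfree_mlp_zero_messages(self, rng):
        g = self.path_graph()
        h = np.zeros((4, 3))
        captured = {}

        def probe_mlp(t):
            captured["m"] = t.numpy().copy()
            return t

        message_pass(h, g, mlp=probe_mlp, gru=GRUCell(3, 3, rng))
        np.testing.assert_array_equal(captured["m"], np.zeros((4, 3)))

    def test_isolated_node_receives_zero_message(self, rng):
        a = np.zeros((3, 3))
        a[0, 1] = 1.0  # node 2 is isolated (no out-edges)
        g = WordGraph(nodes=["a", "b", "c"], adjacency=a,
                      node_index={"a": 0, "b": 1, "c": 2})
        captured = {}

        def probe_mlp(t):
            captured["m"] = t.numpy().copy()
            return t

        message_pass(np.ones((3, 2)), g, mlp=probe_mlp, gru=GRUCell(2, 2, rng))
        np.testing.assert_array_equal(captured["m"][2], np.zeros(2))

    def test_row_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="nodes"):
            message_pass(np.ones((2, 3)), self.path_graph(),
                         mlp=lambda t: t, gru=GRUCell(3, 3, rng))

    @pytest.mark.parametrize("n_nodes", [2, 3, 4, 5, 6])
    def test_propagation_step_oracle_on_all_small_graphs(self, n_nodes):
        """One full step on random graphs of up to 6 nodes agrees with the
        dense formula GRU(H, MLP(D^-1 A H)) evaluated with numpy."""
        rng = np.random.default_rng(100 + n_nodes)
        a = (rng.random((n_nodes, n_nodes)) < 0.5) * rng.integers(
            1, 4, size=(n_nodes, n_nodes)).astype(float)
        np.fill_diagonal(a, 0.0)
        g = WordGraph(nodes=[f"n{i}" for i in range(n_nodes)], adjacency=a,
                      node_index={f"n{i}": i for i in range(n_nodes)})
        h = rng.normal(size=(n_nodes, 4))
        from msmilestone.autodiff import Linear
        lin = Linear(4, 4, rng)
        gru = GRUCell(4, 4, rng)
        out = message_pass(h, g, mlp=lin, gru=gru).numpy()

        deg = a.sum(axis=1)
        dinva = np.where(deg[:, None] > 0, a / np.where(deg[:, None] > 0, deg[:, None], 1), 0.0)
        m = dinva @ h @ lin.weight.data + lin.bias.data

        def sigmoid(x):
            return 1 / (1 + np.exp(-x))
        gi = m @ gru.w_ih.data + gru.b_ih.data
        gh = h @ gru.w_hh.data + gru.b_hh.data
        r = sigmoid(gi[:, :4] + gh[:, :4])
        z = sigmoid(gi[:, 4:8] + gh[:, 4:8])
        nn = np.tanh(gi[:, 8:] + r * gh[:, 8:])
        expected = (1 - z) * nn + z * h
        np.testing.assert_allclose(out, expected, atol=1e-6)


class TestReadout:
    def test_single_word_node_forces_unit_attention(self, rng):
        h = rng.normal(size=(2, 4))  # one word node + document node
        w_a = Tensor(rng.normal(size=(4, 4)))
        v = Tensor(rng.normal(size=4))
        u, beta = readout(h, w_a, v)
        np.testing.assert_allclose(beta.numpy(), [1.0])
        np.testing.assert_allclose(u.numpy(), h[0])

    def test_identical_word_states_share_attention(self, rng):
        row = rng.normal(size=4)
        h = np.stack([row, row, rng.normal(size=4)])
        u, beta = readout(h, Tensor(rng.normal(size=(4, 4))),
                          Tensor(rng.normal(size=4)))
        np.testing.assert_allclose(beta.numpy(), [0.5, 0.5], atol=1e-12)

    def test_random_inputs_match_direct_formula(self, rng):
        h = rng.normal(size=(5, 3))
        w_a = rng.normal(size=(3, 3))
        v = rng.normal(size=3)
        u, beta = readout(h, Tensor(w_a), Tensor(v))
        hw = h[:4]  # document node (last row) removed
        y = np.tanh(hw @ w_a)
        scores = y @ v
        e = np.exp(scores - scores.max())
        b_exp = e / e.sum()
        np.testing.assert_allclose(beta.numpy(), b_exp, atol=1e-10)
        np.testing.assert_allclose(u.numpy(), b_exp @ hw, atol=1e-10)

    def test_attention_sums_to_one(self, rng):
        for n in (2, 4, 9):
            h = rng.normal(size=(n, 6))
            _, beta = readout(h, Tensor(rng.normal(size=(6, 6))),
                              Tensor(rng.normal(size=6)))
            assert abs(beta.numpy().sum() - 1.0) < 1e-6

    def test_document_node_only_rejected(self, rng):
        with pytest.raises(ValueError, match="word node"):
            readout(rng.normal(size=(1, 4)), Tensor(np.eye(4)),
                    Tensor(np.ones(4)))


class TestDocumentEmbedding:
    def test_identical_texts_identical_embeddings(self, rng):
        enc = GraphNoteEncoder(["gait", "worse", "stable"], rng, d_node=8)
        enc.eval()
        text = "gait worse stable gait"
        np.testing.assert_array_equal(enc(text).numpy(), enc(text).numpy())

    def test_reversed_order_changes_embedding(self, rng):
        enc = GraphNoteEncoder([f"w{i}" for i in range(6)], rng, d_node=8)
        enc.eval()
        fwd = "w0 w1 w2 w3 w4 w5"
        rev = "w5 w4 w3 w2 w1 w0"
        assert not np.allclose(enc(fwd).numpy(), enc(rev).numpy())

    def test_one_token_note_equals_propagated_token_state(self, rng):
        """The single word node's readout is its own state after T passes
        through the word<->document two-node graph."""
        enc = GraphNoteEncoder(["gait"], rng, d_node=6, n_passes=2)
        enc.eval()
        g = build_word_graph(["gait"], window=10)
        h = enc.initial_states(g)
        for mlp, gru in zip(enc.mlps, enc.grus):
            h = message_pass(h, g, mlp, gru)
        np.testing.assert_allclose(enc("gait").numpy(), h.numpy()[0], atol=1e-12)

    def test_garbage_text_yields_zero_embedding(self, rng):
        enc = GraphNoteEncoder(["gait"], rng, d_node=8)
        np.testing.assert_array_equal(enc("!!! ??? ").numpy(), np.zeros(8))

    def test_tokenize_lowercases_and_splits_punctuation(self):
        assert tokenize("Gait worsened; EDSS 4.0!") == \
            ["gait", "worsened", "edss", "4", "0"]
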