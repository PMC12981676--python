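"""Graph and sequence encoders against dense independent oracles."""

import numpy as np
import pytest

from kanpm.core_data import WeightedGraph
from kanpm.neural_encoders import (
    GATLayer,
    GCNLayer,
    GraphEncoder,
    GraphEncoderParams,
    SeqEncoderParams,
    TransformerEncoder,
    gcn_norm,
    graph_batch,
)
from kanpm.nn import DTYPE
from kanpm._autodiff import Tensor


def _random_graph(rng, n, p=0.4, d=6):
    feats = rng.standard_normal((n, d))
    edges, weights = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                w = float(rng.uniform(0.5, 2.0))
                edges += [(i, j), (j, i)]
                weights += [w, w]
    if not edges:
        edges, weights = [(0, min(1, n - 1))], [1.0]
        if n > 1:
            edges.append((1, 0)); weights.append(1.0)
        else:
            edges, weights = [], []
    return WeightedGraph(feats, np.array(edges).reshape(-1, 2), weights)


def _dense_gcn_oracle(graph, W, b):
    """Naive D^{-1/2} (A + I) D^{-1/2} H W computation with dense matrices."""
    n = graph.num_nodes
    A = np.zeros((n, n))
    for (i, j), w in zip(graph.edges, graph.edge_weights):
        A[j, i] = w  # message from i into j
    A += np.eye(n)
    deg = A.sum(axis=1)
    Dinv = np.diag(1.0 / np.sqrt(deg))
    return Dinv @ A @ Dinv @ (graph.node_features @ W + b)


class TestGCNLayer:
    def test_matches_dense_oracle(self, rng):
        g = _random_graph(rng, 5)
        layer = GCNLayer(6, 4, np.random.default_rng(0))
        batch = graph_batch([g])
        out = layer.propagate(Tensor(batch.node_features), batch).data
        oracle = _dense_gcn_oracle(
            WeightedGraph(batch.node_features, g.edges, g.edge_weights),
            layer.lin.weight.data.astype(np.float64),
            layer.lin.bias.data.astype(np.float64))
        np.testing.assert_allclose(out, oracle, rtol=1e-4, atol=1e-5)

    def test_isolated_node_is_self_loop_only(self, rng):
        g = WeightedGraph(rng.standard_normal((1, 6)), np.zeros((0, 2), int), [])
        layer = GCNLayer(6, 4, np.random.default_rng(1))
        batch = graph_batch([g])
        out = layer.propagate(Tensor(batch.node_features), batch).data
        expected = batch.node_features.astype(np.float64) @ \
            layer.lin.weight.data + layer.lin.bias.data
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)

    def test_norm_coefficients_sum_consistent(self, rng):
        g = _random_graph(rng, 7)
        coef, self_coef = gcn_norm(g.edges, g.edge_weights, g.num_nodes)
        assert (coef > 0).all() and (self_coef > 0).all()
        # self coefficient equals 1/deg including the unit self-loop
        deg = np.ones(7)
        np.add.at(deg, g.edges[:, 1], g.edge_weights)
        np.testing.assert_allclose(self_coef, 1.0 / deg, rtol=1e-6)


def _dense_gat_oracle(graph, layer):
    """Dense re-implementation of single-head attention over N(i) ∪ {i}."""
    h = graph.node_features @ layer.lin.weight.data.astype(np.float64)
    n = graph.num_nodes
    s_self = h @ layer.att_self.data.astype(np.float64)
    s_neigh = h @ layer.att_neigh.data.astype(np.float64)
    adj = {i: {i} for i in range(n)}
    for i, j in graph.edges:
        adj[j].add(i)  # i is an in-neighbor of j
    out = np.zeros_like(h)
    for i in range(n):
        nbrs = sorted(adj[i])
        logits = np.array([s_self[i] + s_neigh[j] for j in nbrs])
        logits = np.where(logits > 0, logits, layer.slope * logits)
        e = np.exp(logits - logits.max())
        alpha = e / e.sum()
        out[i] = sum(a * h[j] for a, j in zip(alpha, nbrs))
    return out


class TestGATLayer:
    def test_attention_sums_to_one_per_node(self, rng):
        g = _random_graph(rng, 6)
        layer = GATLayer(6, 4, np.random.default_rng(2))
        batch = graph_batch([g])
        alpha, _ = layer.attention(Tensor(batch.node_features), batch.att_edges)
        sums = np.zeros(6)
        np.add.at(sums, batch.att_edges[:, 1], alpha.data)
        np.testing.assert_allclose(sums, 1.0, rtol=1e-5)

    def test_matches_dense_attention_oracle(self, rng):
        g = _random_graph(rng, 4, p=0.7)
        layer = GATLayer(6, 3, np.random.default_rng(3))
        batch = graph_batch([g])
        out = layer.propagate(Tensor(batch.node_features), batch).data
        oracle = _dense_gat_oracle(
            WeightedGraph(batch.node_features, g.edges, g.edge_weights), layer)
        np.testing.assert_allclose(out, oracle, rtol=1e-4, atol=1e-5)

    def test_isolated_node_attends_only_to_itself(self, rng):
        g = WeightedGraph(rng.standard_normal((1, 6)), np.zeros((0, 2), int), [])
        layer = GATLayer(6, 4, np.random.default_rng(4))
        batch = graph_batch([g])
        out = layer.propagate(Tensor(batch.node_features), batch).data
        expected = batch.node_features.astype(np.float64) @ layer.lin.weight.data
        np.testing.assert_allclose(out, expected, rtol=1e-5, atol=1e-6)


class TestGraphEncoder:
    @pytest.fixture
    def encoder(self):
        params = GraphEncoderParams(6, 8, output_dim=5, dropout=0.2)
        return GraphEncoder(params, np.random.default_rng(5)).eval()

    def test_output_width_regardless_of_node_count(self, encoder, rng):
        for n in (1, 3, 9):
            g = _random_graph(rng, n)
            assert encoder.encode(g).shape == (5,)

    def test_permutation_invariance_eval_mode(self, encoder, rng):
        g = _random_graph(rng, 7)
        base = encoder.encode(g)
        for _ in range(10):
            perm = rng.permutation(7)
            inv = np.argsort(perm)
            g2 = WeightedGraph(g.node_features[perm],
                               np.stack([inv[g.edges[:, 0]],
                                         inv[g.edges[:, 1]]], axis=1),
                               g.edge_weights)
            np.testing.assert_allclose(encoder.encode(g2), base,
                                       rtol=1e-3, atol=1e-4)

    def test_add_pool_linearity_on_duplicated_node(self, rng):
        """Duplicating a disconnected graph's single node doubles the pooled
        pre-MLP vector (checked through the linear-only final map)."""
        params = GraphEncoderParams(4, 6, output_dim=3, dropout=0.0)
        enc = GraphEncoder(params, np.random.default_rng(6)).eval()
        x = rng.standard_normal((1, 4))
        g1 = WeightedGraph(x, np.zeros((0, 2), int), [])
        g2 = WeightedGraph(np.vstack([x, x]), np.zeros((0, 2), int), [])
        b1, b2 = graph_batch([g1]), graph_batch([g2])

        def pooled(batch):
            import kanpm._autodiff as ad
            h = Tensor(batch.node_features)
            h = enc.gcn(h, batch)
            for gat in enc.gats:
                h = gat(h, batch)
            return ad.segment_sum(h, batch.graph_ids, batch.n_graphs).data

        np.testing.assert_allclose(pooled(b2), 2 * pooled(b1),
                                   rtol=1e-4, atol=1e-5)

    def test_eval_deterministic_and_finite(self, encoder, rng):
        g = _random_graph(rng, 8)
        a, b = encoder.encode(g), encoder.encode(g)
        np.testing.assert_array_equal(a, b)
        assert np.isfinite(a).all()

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            graph_batch([])


class TestTransformerEncoder:
    @pytest.fixture
    def encoder(self):
        params = SeqEncoderParams(input_dim=10, model_dim=16, n_layers=2,
                                  n_heads=4, ff_dim=16, max_len=30, dropout=0.2)
        return TransformerEncoder(params, np.random.default_rng(7)).eval()

    def test_token_count_preserved(self, encoder, rng):
        x = rng.standard_normal((2, 9, 10)).astype(DTYPE)
        mask = np.ones((2, 9), dtype=bool)
        F, pooled = encoder(x, mask)
        assert F.shape == (2, 9, 16)
        assert pooled.shape == (2, 16)

    def test_padding_does_not_leak_into_real_tokens(self, encoder, rng):
        x = rng.standard_normal((1, 8, 10)).astype(DTYPE)
        mask = np.zeros((1, 8), dtype=bool)
        mask[0, :5] = True
        F1, p1 = encoder(x, mask)
        x2 = x.copy()
        x2[0, 5:] = rng.standard_normal((3, 10))  # perturb only padded rows
        F2, p2 = encoder(x2, mask)
        np.testing.assert_allclose(F1.data[0, :5], F2.data[0, :5],
                                   rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(p1.data, p2.data, rtol=1e-5, atol=1e-6)

    def test_batch_of_one_equals_unbatched(self, encoder, rng):
        xa = rng.standard_normal((6, 10)).astype(DTYPE)
        xb = rng.standard_normal((6, 10)).astype(DTYPE)
        mask = np.ones((2, 6), dtype=bool)
        F_joint, _ = encoder(np.stack([xa, xb]), mask)
        F_solo, _ = encoder(xa[None], np.ones((1, 6), dtype=bool))
        np.testing.assert_allclose(F_joint.data[0], F_solo.data[0],
                                   rtol=1e-4, atol=1e-5)

    def test_all_padding_row_rejected(self, encoder, rng):
        x = rng.standard_normal((2, 4, 10)).astype(DTYPE)
        mask = np.ones((2, 4), dtype=bool)
        mask[1] = False
        with pytest.raises(ValueError, match="all-padding"):
            encoder(x, mask)

    def test_finite_over_many_seeds(self, rng):
        params = SeqEncoderParams(input_dim=5, model_dim=8, n_layers=1,
                                  n_heads=2, ff_dim=8, max_len=10, dropout=0.0)
        for seed in range(100):
            enc = TransformerEncoder(params, np.random.default_rng(seed)).eval()
            x = rng.standard_normal((1, 6, 5)).astype(DTYPE)
            F, pooled = enc(x, np.ones((1, 6), dtype=bool))
            assert np.isfinite(F.data).all() and np.isfinite(pooled.data).all()
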