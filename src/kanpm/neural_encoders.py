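"""The two encoder families: graph encoders and transformer sequence encoders.

Graph encoder (shared architecture for protein residue graphs and molecular
graphs): one weighted GCN layer with symmetric degree normalization and an
added unit self-loop, five stacked single-head GAT layers (attention over
each node's in-neighborhood plus itself; edge weights are not used by
attention), each followed by batch normalization and ReLU; then global add
pooling, dropout and a two-layer MLP down to the output width.

Sequence encoder: a learned projection of the provider embeddings to the
model width, learned positional embeddings, three pre-norm transformer
layers (8-head self-attention + feed-forward) with a padding mask, a final
layer norm, and a masked-mean pooled summary vector exposed for ablations.

Graphs are batched block-diagonally: node rows of all graphs are
concatenated, edge indices offset, and a per-node graph id drives the
segment operations (softmax per neighborhood, add-pool per graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import WeightedGraph
from .nn import DTYPE, BatchNorm1d, Dropout, LayerNorm, Linear, Module, Parameter

__all__ = [
    "GraphEncoderParams",
    "SeqEncoderParams",
    "GraphBatch",
    "graph_batch",
    "gcn_norm",
    "GCNLayer",
    "GATLayer",
    "GraphEncoder",
    "TransformerEncoder",
    "graph_encode",
    "transformer_encode",
]


@dataclass
class GraphEncoderParams:
    input_dim: int
    hidden_dim: int
    output_dim: int = 128
    n_gat_layers: int = 5
    dropout: float = 0.2
    leaky_slope: float = 0.2

    def __post_init__(self):
        if min(self.input_dim, self.hidden_dim, self.output_dim) <= 0:
            raise ValueError("encoder dims must be positive")


@dataclass
class SeqEncoderParams:
    input_dim: int
    model_dim: int = 128
    n_layers: int = 3
    n_heads: int = 8
    ff_dim: int = 128
    max_len: int = 1200
    dropout: float = 0.2

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise ValueError("model_dim must be divisible by n_heads")


# ---------------------------------------------------------------------------
# graph batching
# ---------------------------------------------------------------------------

@dataclass
class GraphBatch:
    """A block-diagonal batch of weighted graphs (all arrays constant)."""

    node_features: np.ndarray   # (N, d)
    edges: np.ndarray           # (E, 2) src,dst after offsetting
    gcn_coef: np.ndarray        # (E,) normalized propagation coefficient
    gcn_self_coef: np.ndarray   # (N,) self-loop coefficient
    att_edges: np.ndarray       # (E + N, 2) edges augmented with self-loops
    graph_ids: np.ndarray       # (N,) graph index per node
    n_graphs: int


def gcn_norm(edges: np.ndarray, weights: np.ndarray, n_nodes: int):
    """Symmetric normalization coefficients for weighted GCN propagation.

    A unit self-loop is added to every node; with dhat_i the weighted degree
    including the self-loop, the edge (j -> i) propagates with coefficient
    w_ij / sqrt(dhat_i dhat_j) and the self-loop with 1 / dhat_i.
    """
    deg = np.ones(n_nodes, dtype=np.float64)  # self-loop weight 1
    if len(edges):
        np.add.at(deg, edges[:, 1], weights)
    inv_sqrt = 1.0 / np.sqrt(deg)
    if len(edges):
        coef = weights * inv_sqrt[edges[:, 0]] * inv_sqrt[edges[:, 1]]
    else:
        coef = np.zeros(0)
    return coef.astype(DTYPE), (1.0 / deg).astype(DTYPE)


def graph_batch(graphs: list[WeightedGraph]) -> GraphBatch:
    """Collate graphs block-diagonally for one encoder forward."""
    if not graphs:
        raise ValueError("empty graph batch")
    feats, edges, ids, coefs, selfs, atts = [], [], [], [], [], []
    offset = 0
    for gi, g in enumerate(graphs):
        if g.num_nodes == 0:
            raise ValueError("graph with zero nodes cannot be encoded")
        feats.append(np.asarray(g.node_features, dtype=DTYPE))
        e = g.edges + offset
        edges.append(e)
        coef, self_coef = gcn_norm(g.edges, g.edge_weights, g.num_nodes)
        coefs.append(coef)
        selfs.append(self_coef)
        loops = np.stack([np.arange(g.num_nodes), np.arange(g.num_nodes)],
                         axis=1) + offset
        atts.append(np.concatenate([e, loops], axis=0))
        ids.append(np.full(g.num_nodes, gi, dtype=np.int64))
        offset += g.num_nodes
    return GraphBatch(
        node_features=np.concatenate(feats, axis=0),
        edges=np.concatenate(edges, axis=0) if edges else np.zeros((0, 2), int),
        gcn_coef=np.concatenate(coefs),
        gcn_self_coef=np.concatenate(selfs),
        att_edges=np.concatenate(atts, axis=0),
        graph_ids=np.concatenate(ids),
        n_graphs=len(graphs),
    )


# ---------------------------------------------------------------------------
# graph layers
# ---------------------------------------------------------------------------

class GCNLayer(Module):
    """Weighted graph convolution with symmetric normalization, then BN+ReLU."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng)
        self.bn = BatchNorm1d(out_dim)

    def propagate(self, x: Tensor, batch: GraphBatch) -> Tensor:
        """Normalized weighted aggregation (pre-BN, pre-activation)."""
        m = self.lin(x)
        n = m.shape[0]
        out = ad.mul(m, Tensor(batch.gcn_self_coef[:, None]))
        if len(batch.edges):
            src, dst = batch.edges[:, 0], batch.edges[:, 1]
            msgs = ad.mul(m[src], Tensor(batch.gcn_coef[:, None]))
            out = ad.add(out, ad.segment_sum(msgs, dst, n))
        return out

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        return ad.relu(self.bn(self.propagate(x, batch)))


class GATLayer(Module):
    """Single-head graph attention over N(i) ∪ {i}, then BN+ReLU.

    Attention logits are LeakyReLU(a^T [W h_i || W h_j]); contact/bond
    weights are deliberately not consumed here.
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 leaky_slope: float = 0.2):
        super().__init__()
        self.lin = Linear(in_dim, out_dim, rng, bias=False)
        self.att_self = Parameter(
            rng.uniform(-1, 1, out_dim) / np.sqrt(out_dim))
        self.att_neigh = Parameter(
            rng.uniform(-1, 1, out_dim) / np.sqrt(out_dim))
        self.bn = BatchNorm1d(out_dim)
        self.slope = leaky_slope

    def attention(self, x: Tensor, att_edges: np.ndarray):
        """Return (alpha, Wh); alpha aligns with att_edges rows."""
        h = self.lin(x)
        n = h.shape[0]
        s_self = ad.matmul(h, ad.reshape(self.att_self, (-1, 1)))
        s_neigh = ad.matmul(h, ad.reshape(self.att_neigh, (-1, 1)))
        src, dst = att_edges[:, 0], att_edges[:, 1]
        logits = ad.leaky_relu(
            ad.add(ad.reshape(s_self, (n,))[dst],
                   ad.reshape(s_neigh, (n,))[src]),
            self.slope,
        )
        alpha = ad.segment_softmax(logits, dst, n)
        return alpha, h

    def propagate(self, x: Tensor, batch: GraphBatch) -> Tensor:
        alpha, h = self.attention(x, batch.att_edges)
        src, dst = batch.att_edges[:, 0], batch.att_edges[:, 1]
        msgs = ad.mul(h[src], ad.reshape(alpha, (-1, 1)))
        return ad.segment_sum(msgs, dst, h.shape[0])

    def __call__(self, x: Tensor, batch: GraphBatch) -> Tensor:
        return ad.relu(self.bn(self.propagate(x, batch)))


class GraphEncoder(Module):
    """GCN -> 5x GAT -> global add pool -> dropout -> 2-layer MLP."""

    def __init__(self, params: GraphEncoderParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.gcn = GCNLayer(params.input_dim, params.hidden_dim, rng)
        self.gats = [
            GATLayer(params.hidden_dim, params.hidden_dim, rng,
                     params.leaky_slope)
            for _ in range(params.n_gat_layers)
        ]
        self.drop = Dropout(params.dropout, rng)
        self.fc1 = Linear(params.hidden_dim, params.hidden_dim, rng)
        self.fc2 = Linear(params.hidden_dim, params.output_dim, rng)

    def __call__(self, batch: GraphBatch) -> Tensor:
        x = Tensor(batch.node_features)
        x = self.gcn(x, batch)
        for gat in self.gats:
            x = gat(x, batch)
        pooled = ad.segment_sum(x, batch.graph_ids, batch.n_graphs)
        pooled = self.drop(pooled)
        return self.fc2(ad.relu(self.fc1(pooled)))

    def encode(self, graph: WeightedGraph) -> np.ndarray:
        """Eval-mode convenience for a single graph."""
        mode = self.training
        self.eval()
        try:
            out = self(graph_batch([graph])).data[0]
        finally:
            self.train(mode)
        return out


def graph_encode(graph: WeightedGraph, params: GraphEncoderParams,
                 seed: int = 0) -> np.ndarray:
    """Functional form: encode one graph with a freshly seeded encoder."""
    enc = GraphEncoder(params, np.random.default_rng(seed))
    return enc.encode(graph)


# ---------------------------------------------------------------------------
# transformer sequence encoder
# ---------------------------------------------------------------------------

class _TransformerLayer(Module):
    def __init__(self, dim: int, n_heads: int, ff_dim: int,
                 rng: np.random.Generator, dropout_p: float):
        super().__init__()
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)
        self.ff1 = Linear(dim, ff_dim, rng)
        self.ff2 = Linear(ff_dim, dim, rng)
        self.drop = Dropout(dropout_p, rng)

    def _attend(self, x: Tensor, neg_mask: np.ndarray) -> Tensor:
        B, L, D = x.shape
        H, hd = self.n_heads, self.head_dim

        def split(t):  # (B,L,D) -> (B,H,L,hd)
            return ad.transpose(ad.reshape(t, (B, L, H, hd)), (0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        # fold the 1/sqrt(hd) scale into q (cheaper than scaling the LxL scores)
        scores = ad.matmul(ad.mul(q, 1.0 / np.sqrt(hd)),
                           ad.transpose(k, (0, 1, 3, 2)))
        alpha = ad.softmax_lastaxis(scores, additive_mask=neg_mask)
        out = ad.matmul(alpha, v)                      # (B,H,L,hd)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (B, L, D))
        return self.wo(out)

    def __call__(self, x: Tensor, neg_mask: np.ndarray) -> Tensor:
        x = ad.add(x, self.drop(self._attend(self.ln1(x), neg_mask)))
        h = self.ff2(ad.relu(self.ff1(self.ln2(x))))
        return ad.add(x, self.drop(h))


class TransformerEncoder(Module):
    """Pre-norm transformer over projected provider embeddings.

    ``forward(x, mask)`` takes a padded batch (B, L, provider_dim) and a
    boolean mask of real tokens, and returns (token features (B, L, dm),
    masked-mean pooled vector (B, dm)).
    """

    def __init__(self, params: SeqEncoderParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.proj = Linear(params.input_dim, params.model_dim, rng, bias=False)
        self.pos = Parameter(
            rng.standard_normal((params.max_len, params.model_dim)) * 0.02)
        self.layers = [
            _TransformerLayer(params.model_dim, params.n_heads, params.ff_dim,
                              rng, params.dropout)
            for _ in range(params.n_layers)
        ]
        self.ln_final = LayerNorm(params.model_dim)

    def __call__(self, x, mask: np.ndarray):
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))
        mask = np.asarray(mask, dtype=bool)
        B, L, _ = x.shape
        if L > self.params.max_len:
            raise ValueError(
                f"sequence length {L} exceeds positional table "
                f"{self.params.max_len}; truncate during batching"
            )
        if not mask.any(axis=1).all():
            raise ValueError("batch contains an all-padding row")
        h = ad.add(self.proj(x), self.pos[:L])
        # additive attention mask: large negative at padded key positions
        neg = np.where(mask, 0.0, -1e9).astype(DTYPE)[:, None, None, :]
        for layer in self.layers:
            h = layer(h, neg)
        h = self.ln_final(h)
        m = mask.astype(DTYPE)[:, :, None]
        pooled = ad.div(ad.tsum(ad.mul(h, Tensor(m)), axis=1),
                        Tensor(m.sum(axis=1)))
        return h, pooled


def transformer_encode(embeddings: np.ndarray, mask: np.ndarray,
                       params: SeqEncoderParams, seed: int = 0):
    """Functional form: encode one padded batch with a fresh eval-mode model."""
    enc = TransformerEncoder(params, np.random.default_rng(seed)).eval()
    F, pooled = enc(np.asarray(embeddings, dtype=DTYPE), mask)
    return F.data, pooled.data
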