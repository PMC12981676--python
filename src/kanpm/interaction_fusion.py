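"""Adaptive feature learning: gated fusion, linear-attention pooling,
cross-modal attention and assembly of the joint vector.

The two graph-level embeddings H_d (drug) and H_p (protein) are combined by
a learned sigmoid gate into an elementwise convex combination A_g.  The two
transformer token sequences are each distilled to a fixed-width vector by
additive (tanh-scorer) attention pooling (A_d, A_t); the pair [A_d, A_t] is
treated as a 2-token sequence and pooled again by the same operator to give
the cross-modal summary A_dt.  The joint representation is the fixed-order
concatenation Z = [A_g, A_d, A_t, A_dt]; ablation switches drop or replace
blocks and shrink Z accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .nn import DTYPE, Linear, Module, Parameter

__all__ = [
    "FusionParams",
    "GatedFusion",
    "LinearAttentionPool",
    "cross_attention",
    "masked_mean",
    "InteractionFusion",
]


@dataclass
class FusionParams:
    dim: int = 128
    att_dim: int = 64


class GatedFusion(Module):
    """A_g = g ⊙ H_d + (1-g) ⊙ H_p with gate g = σ(W_g [H_d; H_p]).

    The gate output is strictly inside (0,1) elementwise, so A_g is a
    coordinatewise convex combination of its two inputs.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        super().__init__()
        self.gate = Linear(2 * dim, dim, rng, bias=False)

    def __call__(self, h_d: Tensor, h_p: Tensor) -> Tensor:
        if h_d.shape != h_p.shape:
            raise ValueError(
                f"gated fusion width mismatch: {h_d.shape} vs {h_p.shape}")
        g = ad.sigmoid(self.gate(ad.concat([h_d, h_p], axis=-1)))
        return ad.add(ad.mul(g, h_d), ad.mul(ad.add(ad.mul(g, -1.0), 1.0), h_p))


class LinearAttentionPool(Module):
    """Additive attention pooling of a token sequence to one vector.

    Scores s_i = v^T tanh(W f_i) on unmasked tokens; α = softmax(s);
    output Σ_i α_i f_i.  Permutation-invariant in (tokens, mask).
    """

    def __init__(self, dim: int, att_dim: int, rng: np.random.Generator):
        super().__init__()
        self.scorer = Linear(dim, att_dim, rng, bias=False)
        self.v = Parameter(rng.uniform(-1, 1, att_dim) / np.sqrt(att_dim))

    def __call__(self, f: Tensor, mask: np.ndarray | None = None) -> Tensor:
        """``f``: (B, L, dim); ``mask``: boolean (B, L) or None (all real)."""
        f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=DTYPE))
        B, L, _ = f.shape
        if mask is None:
            mask = np.ones((B, L), dtype=bool)
        mask = np.asarray(mask, dtype=bool)
        if not mask.any(axis=1).all():
            raise ValueError("attention pool over an all-masked sequence")
        s = ad.matmul(ad.tanh(self.scorer(f)), ad.reshape(self.v, (-1, 1)))
        s = ad.reshape(s, (B, L))
        alpha = ad.softmax_lastaxis(
            s, additive_mask=np.where(mask, 0.0, -1e9).astype(DTYPE))
        return ad.tsum(ad.mul(f, ad.reshape(alpha, (B, L, 1))), axis=1)

    def weights(self, f, mask=None) -> np.ndarray:
        """Attention weights alpha (B, L) for inspection/testing."""
        f = f if isinstance(f, Tensor) else Tensor(np.asarray(f, dtype=DTYPE))
        B, L, _ = f.shape
        if mask is None:
            mask = np.ones((B, L), dtype=bool)
        s = ad.reshape(
            ad.matmul(ad.tanh(self.scorer(f)), ad.reshape(self.v, (-1, 1))),
            (B, L))
        alpha = ad.softmax_lastaxis(
            s, additive_mask=np.where(mask, 0.0, -1e9).astype(DTYPE))
        return alpha.data


def cross_attention(a_d: Tensor, a_t: Tensor,
                    pool: LinearAttentionPool) -> Tensor:
    """Pool the pair [A_d, A_t] as a 2-token sequence with ``pool``."""
    if a_d.shape != a_t.shape:
        raise ValueError(
            f"cross attention width mismatch: {a_d.shape} vs {a_t.shape}")
    seq = ad.stack([a_d, a_t], axis=1)  # (B, 2, dim)
    return pool(seq)


def masked_mean(f: Tensor, mask: np.ndarray) -> Tensor:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=1).all():
        raise ValueError("masked mean over an all-masked sequence")
    m = mask.astype(DTYPE)[:, :, None]
    return ad.div(ad.tsum(ad.mul(f, Tensor(m)), axis=1), Tensor(m.sum(axis=1)))


class InteractionFusion(Module):
    """Assemble the joint vector Z from the four block outputs, honoring
    the ablation switches.

    Full model: Z = [A_g, A_d, A_t, A_dt], width 4 x dim.  Ablations:
    dropping the graph branch removes A_g; dropping the sequence branch
    removes A_d/A_t/A_dt; without gated fusion A_g is replaced by a linear
    reduction of [H_d; H_p]; without linear attention A_d/A_t become masked
    means and the cross block is dropped (plain concatenation).
    """

    def __init__(self, graph_dim: int, seq_dim: int, att_dim: int,
                 rng: np.random.Generator, *,
                 use_graph: bool = True, use_sequence: bool = True,
                 use_linear_attention: bool = True,
                 use_gated_fusion: bool = True):
        super().__init__()
        if not (use_graph or use_sequence):
            raise ValueError("all fusion blocks disabled: empty model")
        self.graph_dim = graph_dim
        self.seq_dim = seq_dim
        self.use_graph = use_graph
        self.use_sequence = use_sequence
        self.use_linear_attention = use_linear_attention
        self.use_gated_fusion = use_gated_fusion
        if use_graph:
            if use_gated_fusion:
                self.gated = GatedFusion(graph_dim, rng)
            else:
                self.reduce = Linear(2 * graph_dim, graph_dim, rng)
        if use_sequence and use_linear_attention:
            self.pool_drug = LinearAttentionPool(seq_dim, att_dim, rng)
            self.pool_prot = LinearAttentionPool(seq_dim, att_dim, rng)
            self.pool_cross = LinearAttentionPool(seq_dim, att_dim, rng)

    @property
    def z_dim(self) -> int:
        width = self.graph_dim if self.use_graph else 0
        if self.use_sequence:
            width += (3 if self.use_linear_attention else 2) * self.seq_dim
        return width

    def __call__(self, h_d=None, h_p=None, f_s=None, mask_s=None,
                 f_t=None, mask_t=None) -> Tensor:
        parts = []
        if self.use_graph:
            if self.use_gated_fusion:
                parts.append(self.gated(h_d, h_p))
            else:
                parts.append(self.reduce(ad.concat([h_d, h_p], axis=-1)))
        if self.use_sequence:
            if self.use_linear_attention:
                a_d = self.pool_drug(f_s, mask_s)
                a_t = self.pool_prot(f_t, mask_t)
                parts.extend([a_d, a_t, cross_attention(a_d, a_t, self.pool_cross)])
            else:
                parts.extend([masked_mean(f_s, mask_s),
                              masked_mean(f_t, mask_t)])
        return ad.concat(parts, axis=-1)
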