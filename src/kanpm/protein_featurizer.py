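"""Residue-level protein graph construction from contact-probability maps.

Edges connect residue pairs whose (symmetrized) contact probability strictly
exceeds a threshold (default 0.5); edge weights are the probabilities
themselves and node features are the provider's residue embeddings with any
start/end special tokens trimmed off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_data import AMINO_ACIDS, ProteinRecord, WeightedGraph

__all__ = [
    "ContactGraphSpec",
    "trim_special_tokens",
    "build_protein_graph",
    "residue_onehot",
    "pad_token_batch",
    "pad_protein_batch",
]


@dataclass
class ContactGraphSpec:
    threshold: float = 0.5
    symmetrize: bool = True
    include_self_loops: bool = False

    def __post_init__(self):
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def trim_special_tokens(embeddings: np.ndarray,
                        has_special_tokens: bool) -> np.ndarray:
    """Drop the start/end special-token rows so rows align with residues.

    A flagged (token_count x d) matrix keeps rows 1..token_count-2; an
    unflagged matrix is returned unchanged.
    """
    embeddings = np.asarray(embeddings)
    if not has_special_tokens:
        return embeddings
    if embeddings.shape[0] < 3:
        raise ValueError(
            "matrix flagged as carrying special tokens must have >= 3 rows"
        )
    return embeddings[1:-1]


def build_protein_graph(record: ProteinRecord,
                        spec: ContactGraphSpec = ContactGraphSpec(),
                        node_features: np.ndarray | None = None,
                        ) -> WeightedGraph:
    """Build the weighted residue graph of a protein.

    Node features are the trimmed provider embeddings (or an explicit
    ``node_features`` override, e.g. residue one-hots for the ablation that
    drops language-model features).  The contact matrix may be residue- or
    token-indexed; a token-indexed matrix has the same 1..n-2 window cut
    from both axes.  Asymmetric matrices are symmetrized as (M + M^T)/2
    before the strictly-greater-than threshold is applied.
    """
    n_res = len(record.sequence)
    feats = trim_special_tokens(record.embeddings, record.has_special_tokens)
    if node_features is not None:
        feats = np.asarray(node_features)
    M = record.contact
    if M.shape[0] != M.shape[1]:
        raise ValueError("contact matrix must be square")
    if M.shape[0] == n_res + 2 and record.has_special_tokens:
        M = M[1:-1, 1:-1]
    if M.shape[0] != feats.shape[0]:
        raise ValueError(
            f"contact side {M.shape[0]} != node count {feats.shape[0]} "
            "after special-token trimming"
        )
    if spec.symmetrize:
        M = 0.5 * (M + M.T)
    mask = M > spec.threshold
    if not spec.include_self_loops:
        np.fill_diagonal(mask, False)
    src, dst = np.nonzero(mask)
    edges = np.stack([src, dst], axis=1)
    weights = M[src, dst]
    return WeightedGraph(feats, edges, weights)


_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS + "X")}


def residue_onehot(sequence: str) -> np.ndarray:
    """One-hot residue identities (20 amino acids + X), shape (L, 21)."""
    out = np.zeros((len(sequence), len(_AA_INDEX)))
    for i, aa in enumerate(sequence.upper()):
        out[i, _AA_INDEX[aa]] = 1.0
    return out


def pad_token_batch(items, cap: int):
    """Pad a non-empty list of (L_i x d) matrices to a common length.

    Returns ``(batch, mask)``: ``batch`` of shape (B, L, d) with
    L = min(max L_i, cap), and a boolean ``mask`` (B, L) marking real
    tokens.  Sequences longer than ``cap`` are truncated at ``cap``.
    """
    items = [np.asarray(x) for x in items]
    if not items:
        raise ValueError("empty batch")
    if any(x.ndim != 2 for x in items):
        raise ValueError("each batch item must be a 2-D (tokens x dim) matrix")
    dims = {x.shape[1] for x in items}
    if len(dims) != 1:
        raise ValueError(f"inconsistent feature widths in batch: {sorted(dims)}")
    L = min(max(x.shape[0] for x in items), cap)
    d = items[0].shape[1]
    batch = np.zeros((len(items), L, d), dtype=items[0].dtype)
    mask = np.zeros((len(items), L), dtype=bool)
    for i, x in enumerate(items):
        m = min(x.shape[0], L)
        batch[i, :m] = x[:m]
        mask[i, :m] = True
    return batch, mask


def pad_protein_batch(items, cap: int = 1200):
    """Protein-side batch padding (cap = maximum supported residue length)."""
    return pad_token_batch(items, cap)
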