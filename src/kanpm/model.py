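"""Full drug-target affinity model: featurization caches, forward pass,
prediction and checkpoint serialization.

The model encodes each *entity* (protein or drug) once per batch and
gathers the entity representations onto the interaction pairs, which makes
CPU training on dense pair grids (many pairs per entity) practical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .core_data import DrugRecord, ModelConfig, ProteinRecord
from .nn import DTYPE, Module
from .neural_encoders import (
    GraphBatch,
    GraphEncoder,
    GraphEncoderParams,
    SeqEncoderParams,
    TransformerEncoder,
    graph_batch,
)
from .interaction_fusion import InteractionFusion
from .kan_head import make_head
from .protein_featurizer import (
    ContactGraphSpec,
    build_protein_graph,
    residue_onehot,
    trim_special_tokens,
)

__all__ = ["DTAModel", "DatasetTensors", "save_checkpoint", "load_checkpoint"]


class DatasetTensors:
    """Per-entity featurization cache for a (proteins, drugs) universe.

    Protein graphs use trimmed provider embeddings as node features (or
    residue one-hots when the language-model-features ablation is off);
    token sequences keep any special tokens.  Entities longer than the
    configured caps are truncated.
    """

    def __init__(self, proteins: list[ProteinRecord], drugs: list[DrugRecord],
                 config: ModelConfig):
        self.config = config
        self.protein_ids = [p.protein_id for p in proteins]
        self.drug_ids = [d.drug_id for d in drugs]
        self.p_index = {pid: i for i, pid in enumerate(self.protein_ids)}
        self.d_index = {did: i for i, did in enumerate(self.drug_ids)}
        spec = ContactGraphSpec()

        self.protein_graphs = []
        self.protein_tokens = []
        for p in proteins:
            cap = config.protein_max_len
            feats = None
            if not config.use_esmc_node_features:
                feats = residue_onehot(p.sequence)
            g = build_protein_graph(p, spec, node_features=feats)
            if g.num_nodes > cap:  # graph built on the truncated window
                keep = (g.edges[:, 0] < cap) & (g.edges[:, 1] < cap)
                from .core_data import WeightedGraph
                g = WeightedGraph(g.node_features[:cap], g.edges[keep],
                                  g.edge_weights[keep])
            self.protein_graphs.append(g)
            tokens = np.asarray(p.embeddings, dtype=DTYPE)
            self.protein_tokens.append(tokens[: cap + 2])
        self.drug_graphs = [d.graph for d in drugs]
        self.drug_tokens = [
            np.asarray(d.embeddings, dtype=DTYPE)[: config.drug_max_len]
            for d in drugs
        ]

    # -- batching ---------------------------------------------------------
    def collate(self, pairs):
        """Build one training batch from (protein_idx, drug_idx) pairs.

        Entities are deduplicated: each unique protein/drug is encoded once
        and an inverse index maps encodings back onto the pairs.
        """
        p_idx = np.asarray([p for p, _ in pairs])
        d_idx = np.asarray([d for _, d in pairs])
        up, p_inv = np.unique(p_idx, return_inverse=True)
        ud, d_inv = np.unique(d_idx, return_inverse=True)

        batch = {"p_inv": p_inv, "d_inv": d_inv}
        cfg = self.config
        if cfg.use_graph:
            batch["p_graphs"] = graph_batch([self.protein_graphs[i] for i in up])
            batch["d_graphs"] = graph_batch([self.drug_graphs[i] for i in ud])
        if cfg.use_sequence:
            from .protein_featurizer import pad_token_batch

            batch["p_tokens"], batch["p_mask"] = pad_token_batch(
                [self.protein_tokens[i] for i in up], cfg.protein_max_len + 2)
            batch["d_tokens"], batch["d_mask"] = pad_token_batch(
                [self.drug_tokens[i] for i in ud], cfg.drug_max_len)
        return batch


class DTAModel(Module):
    """Graph + sequence encoders, gated fusion / linear attention, and the
    KAN (or MLP) regression head, wired per :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        fd = config.fusion_dim
        if config.use_graph:
            p_in = config.protein_graph_in if config.use_esmc_node_features else 21
            self.protein_graph_enc = GraphEncoder(GraphEncoderParams(
                p_in, config.protein_graph_hidden, config.protein_graph_out,
                dropout=config.dropout), rng)
            self.drug_graph_enc = GraphEncoder(GraphEncoderParams(
                config.drug_graph_in, config.drug_graph_hidden,
                config.drug_graph_out, dropout=config.dropout), rng)
        if config.use_sequence:
            self.protein_seq_enc = TransformerEncoder(SeqEncoderParams(
                config.protein_embed_dim, config.tf_dim, config.tf_layers,
                config.tf_heads, config.tf_ff_dim,
                max_len=config.protein_max_len + 2,
                dropout=config.dropout), rng)
            self.drug_seq_enc = TransformerEncoder(SeqEncoderParams(
                config.drug_embed_dim, config.tf_dim, config.tf_layers,
                config.tf_heads, config.tf_ff_dim,
                max_len=config.drug_max_len, dropout=config.dropout), rng)
        if config.use_graph and config.protein_graph_out != config.drug_graph_out:
            raise ValueError(
                "gated fusion needs equal protein/drug graph output widths")
        self.fusion = InteractionFusion(
            fd, config.tf_dim, config.fusion_att_dim, rng,
            use_graph=config.use_graph, use_sequence=config.use_sequence,
            use_linear_attention=config.use_linear_attention,
            use_gated_fusion=config.use_gated_fusion)
        self.head = make_head(self.fusion.z_dim, config.kan_hidden,
                              config.use_kan, rng,
                              config.kan_grid_size, config.kan_spline_order)

    def __call__(self, batch: dict) -> Tensor:
        cfg = self.config
        h_d = h_p = f_s = f_t = None
        mask_s = mask_t = None
        p_inv, d_inv = batch["p_inv"], batch["d_inv"]
        if cfg.use_graph:
            h_p = self.protein_graph_enc(batch["p_graphs"])[p_inv]
            h_d = self.drug_graph_enc(batch["d_graphs"])[d_inv]
        if cfg.use_sequence:
            f_t_u, _ = self.protein_seq_enc(batch["p_tokens"], batch["p_mask"])
            f_s_u, _ = self.drug_seq_enc(batch["d_tokens"], batch["d_mask"])
            # sequence-branch token features, gathered per pair
            f_t, mask_t = f_t_u[p_inv], batch["p_mask"][p_inv]
            f_s, mask_s = f_s_u[d_inv], batch["d_mask"][d_inv]
        z = self.fusion(h_d=h_d, h_p=h_p, f_s=f_s, mask_s=mask_s,
                        f_t=f_t, mask_t=mask_t)
        return self.head(z)

    # -- inference --------------------------------------------------------
    def predict(self, tensors: DatasetTensors, pairs,
                batch_size: int = 256) -> np.ndarray:
        """Eval-mode predictions for (protein_idx, drug_idx) pairs."""
        mode = self.training
        self.eval()
        try:
            out = []
            for lo in range(0, len(pairs), batch_size):
                chunk = pairs[lo:lo + batch_size]
                out.append(self(tensors.collate(chunk)).data)
        finally:
            self.train(mode)
        return np.concatenate(out) if out else np.zeros(0)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: DTAModel, extra: dict | None = None):
    """Serialize weights + config (architecture travels with the weights)."""
    path = Path(path)
    meta = {"config": model.config.to_dict(), "extra": extra or {}}
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> tuple[DTAModel, dict]:
    path = Path(path)
    with np.load(path if str(path).endswith(".npz") else f"{path}.npz") as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    config = ModelConfig.from_dict(meta["config"])
    model = DTAModel(config)
    model.load_state_dict(state)
    model.eval()
    return model, meta["extra"]
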