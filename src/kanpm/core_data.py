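"""Domain types and file I/O for the drug-target affinity pipeline.

The package's in-memory currency:

* :class:`ProteinRecord` -- a target protein: amino-acid sequence, a
  residue/token embedding matrix from a protein language model (width 1152
  for the standard provider), and a square contact-probability matrix.
* :class:`DrugRecord` -- a small molecule: SMILES, token-embedding matrix
  (width 384 for the standard provider) and its molecular graph.
* :class:`WeightedGraph` -- one container for both protein residue graphs and
  molecular graphs: node features, a directed edge list and per-edge weights.
* :class:`InteractionRecord` -- one (drug, protein, affinity) measurement.
* :class:`ModelConfig` -- every architecture/training hyperparameter plus
  the ablation switches.

File formats are the field's plain-text standards: FASTA for proteins,
CSV/TSV tables for drugs and interactions, NPY or whitespace text for dense
matrices.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "AMINO_ACIDS",
    "ProteinRecord",
    "DrugRecord",
    "WeightedGraph",
    "InteractionRecord",
    "ModelConfig",
    "read_fasta",
    "read_interaction_table",
    "read_drug_table",
    "read_matrix",
    "write_matrix",
    "write_predictions",
    "read_predictions",
    "pkd_from_kd_nm",
]

#: the 20 canonical residues; X marks unknown/ambiguous residues
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET = set(AMINO_ACIDS) | {"X"}

# standard provider widths (protein language model / chemical language model /
# atom feature scheme)
PROTEIN_EMBED_DIM = 1152
DRUG_EMBED_DIM = 384
ATOM_FEATURE_DIM = 88


@dataclass
class WeightedGraph:
    """Directed weighted graph; undirected bonds/contacts store both arcs."""

    node_features: np.ndarray  # (num_nodes, feat_dim)
    edges: np.ndarray          # (num_edges, 2) int, ordered (src, dst)
    edge_weights: np.ndarray   # (num_edges,) float, all > 0

    def __post_init__(self):
        self.node_features = np.asarray(self.node_features, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_weights = np.asarray(self.edge_weights, dtype=np.float64).ravel()
        if self.node_features.ndim != 2:
            raise ValueError("node_features must be a 2-D matrix")
        n = self.num_nodes
        if len(self.edges) != len(self.edge_weights):
            raise ValueError("edge_weights length must equal number of edges")
        if len(self.edges) and (self.edges.min() < 0 or self.edges.max() >= n):
            raise ValueError("edge indices out of range")
        if len(self.edge_weights) and not np.all(self.edge_weights > 0):
            raise ValueError("edge weights must be strictly positive")

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return len(self.edges)


@dataclass
class ProteinRecord:
    """A protein with provider embeddings and a contact-probability matrix.

    ``has_special_tokens`` declares whether the embedding matrix carries
    start/end special tokens (token_count = len(sequence) + 2); the contact
    matrix may be residue- or token-indexed and is validated against both.
    """

    protein_id: str
    sequence: str
    embeddings: np.ndarray        # (token_count, embed_dim)
    contact: np.ndarray           # (side, side), entries in [0, 1]
    has_special_tokens: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id!r}: illegal residues {sorted(bad)}"
            )
        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        self.contact = np.asarray(self.contact, dtype=np.float64)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a 2-D matrix")
        expected = len(self.sequence) + (2 if self.has_special_tokens else 0)
        if self.embeddings.shape[0] != expected:
            raise ValueError(
                f"protein {self.protein_id!r}: embedding rows "
                f"{self.embeddings.shape[0]} != expected token count {expected}"
            )
        if self.contact.ndim != 2 or self.contact.shape[0] != self.contact.shape[1]:
            raise ValueError("contact matrix must be square")
        if self.contact.shape[0] not in (len(self.sequence), expected):
            raise ValueError(
                f"protein {self.protein_id!r}: contact side {self.contact.shape[0]} "
                f"matches neither residue count nor token count"
            )
        if not np.all(np.isfinite(self.contact)):
            raise ValueError("contact matrix has non-finite entries")
        if self.contact.min() < 0 or self.contact.max() > 1:
            raise ValueError("contact probabilities must lie in [0, 1]")

    @property
    def token_count(self) -> int:
        return self.embeddings.shape[0]


@dataclass
class DrugRecord:
    drug_id: str
    smiles: str
    embeddings: np.ndarray               # (token_count, embed_dim)
    graph: Optional[WeightedGraph] = None

    def __post_init__(self):
        from rdkit import Chem  # local import keeps module import light

        self.embeddings = np.asarray(self.embeddings, dtype=np.float64)
        if self.embeddings.ndim != 2:
            raise ValueError("embeddings must be a 2-D matrix")
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValueError(f"drug {self.drug_id!r}: invalid SMILES {self.smiles!r}")


@dataclass
class InteractionRecord:
    drug_id: str
    protein_id: str
    affinity: float

    def __post_init__(self):
        self.affinity = float(self.affinity)
        if not np.isfinite(self.affinity):
            raise ValueError(
                f"non-finite affinity for ({self.drug_id}, {self.protein_id})"
            )


@dataclass
class ModelConfig:
    """All architecture and training hyperparameters, plus ablation switches.

    Defaults are the full-scale settings; :meth:`tiny` returns a desk-scale
    preset with the same architecture but small widths, suitable for CPU runs
    on synthetic data.
    """

    # training
    epochs: int = 200
    lr: float = 1e-4
    batch_size: int = 16
    dropout: float = 0.2
    patience: int = 20
    seed: int = 0
    # transformer sequence encoders
    tf_layers: int = 3
    tf_heads: int = 8
    tf_dim: int = 128
    tf_ff_dim: int = 128
    protein_max_len: int = 1200
    drug_max_len: int = 220
    # graph encoders
    protein_graph_in: int = PROTEIN_EMBED_DIM
    protein_graph_hidden: int = 256
    protein_graph_out: int = 128
    drug_graph_in: int = ATOM_FEATURE_DIM
    drug_graph_hidden: int = 128
    drug_graph_out: int = 128
    # provider widths
    protein_embed_dim: int = PROTEIN_EMBED_DIM
    drug_embed_dim: int = DRUG_EMBED_DIM
    # fusion / head
    fusion_att_dim: int = 64
    kan_grid_size: int = 5
    kan_spline_order: int = 3
    kan_hidden: tuple = (256, 64)
    # ablation switches
    use_graph: bool = True
    use_sequence: bool = True
    use_linear_attention: bool = True
    use_gated_fusion: bool = True
    use_esmc_node_features: bool = True
    use_kan: bool = True

    def __post_init__(self):
        for f in ("tf_layers", "tf_heads", "tf_dim", "tf_ff_dim", "batch_size",
                  "protein_graph_hidden", "protein_graph_out",
                  "drug_graph_hidden", "drug_graph_out", "epochs"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.tf_dim % self.tf_heads:
            raise ValueError("tf_dim must be divisible by tf_heads")
        if not any((self.use_graph, self.use_sequence)):
            raise ValueError("at least one of graph/sequence branches required")

    @property
    def fusion_dim(self) -> int:
        # graph and sequence block widths must agree for gated fusion / concat
        return self.protein_graph_out

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        """Desk-scale preset: same architecture, small widths, CPU-friendly
        optimization settings (larger batches, higher learning rate)."""
        base = dict(
            epochs=150, lr=1e-3, batch_size=128, patience=25,
            tf_dim=32, tf_ff_dim=32, tf_heads=8,
            protein_graph_hidden=32, protein_graph_out=32,
            drug_graph_hidden=32, drug_graph_out=32,
            fusion_att_dim=16, kan_hidden=(64, 16),
        )
        base.update(overrides)
        return cls(**base)

    def with_ablation(self, **flags) -> "ModelConfig":
        return replace(self, **flags)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        kwargs = dict(d)
        if "kan_hidden" in kwargs:
            kwargs["kan_hidden"] = tuple(kwargs["kan_hidden"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (protein_id, sequence) pairs.

    Sequences are uppercased and validated against the 20-letter alphabet
    plus X; duplicate ids and empty files are rejected.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA (no records)")
    out, seen = [], set()
    for rec in records:
        pid = rec.id
        if pid in seen:
            raise ValueError(f"{path}: duplicate protein id {pid!r}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALPHABET
        if bad:
            raise ValueError(
                f"{path}: protein {pid!r} has illegal residues {sorted(bad)}"
            )
        out.append((pid, seq))
    return out


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_table(path, required: Sequence[str]) -> list[dict]:
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    found = reader.fieldnames or []
    missing = [c for c in required if c not in found]
    if missing:
        raise ValueError(
            f"{path}: missing columns {missing}; found columns {found}"
        )
    return list(reader)


def read_interaction_table(path) -> list[InteractionRecord]:
    """Read a delimited drug_id/protein_id/affinity table (CSV or TSV)."""
    rows = _read_table(path, ["drug_id", "protein_id", "affinity"])
    out = []
    for i, row in enumerate(rows, start=2):  # row 1 is the header
        try:
            aff = float(row["affinity"])
        except (TypeError, ValueError):
            raise ValueError(
                f"{path}: row {i}: non-numeric affinity {row['affinity']!r}"
            ) from None
        out.append(InteractionRecord(row["drug_id"], row["protein_id"], aff))
    return out


def read_drug_table(path) -> list[tuple[str, str]]:
    """Read a delimited drug_id/smiles table into (drug_id, smiles) pairs."""
    rows = _read_table(path, ["drug_id", "smiles"])
    out, seen = [], set()
    for row in rows:
        did = row["drug_id"]
        if did in seen:
            raise ValueError(f"{path}: duplicate drug id {did!r}")
        seen.add(did)
        out.append((did, row["smiles"]))
    return out


def read_matrix(path) -> np.ndarray:
    """Load a dense 2-D real matrix from NPY binary or whitespace text."""
    path = Path(path)
    if path.suffix == ".npy":
        mat = np.load(path)
    else:
        try:
            mat = np.loadtxt(path, ndmin=2)
        except ValueError as exc:
            raise ValueError(f"{path}: malformed matrix text ({exc})") from None
        # np.loadtxt(ndmin=2) lifts 1-D rows; re-check the raw rank
        with open(path) as fh:
            n_cols = {len(line.split()) for line in fh if line.strip()}
        if len(n_cols) > 1:
            raise ValueError(f"{path}: ragged rows (column counts {sorted(n_cols)})")
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError(f"{path}: expected a rank-2 matrix, got rank {mat.ndim}")
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path}: matrix has non-finite entries")
    return mat.astype(np.float64)


def write_matrix(path, mat: np.ndarray):
    path = Path(path)
    mat = np.asarray(mat)
    if mat.ndim != 2:
        raise ValueError("only rank-2 matrices are written")
    if path.suffix == ".npy":
        np.save(path, mat)
    else:
        np.savetxt(path, mat)


def write_predictions(records, path):
    """Write (drug_id, protein_id, y_true-or-None, y_pred) rows as CSV.

    y_true of None is serialized as an empty field; values use 6 decimals.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["drug_id", "protein_id", "y_true", "y_pred"])
        for did, pid, y_true, y_pred in records:
            yt = "" if y_true is None else f"{float(y_true):.6f}"
            w.writerow([did, pid, yt, f"{float(y_pred):.6f}"])


def read_predictions(path) -> list[tuple[str, str, Optional[float], float]]:
    rows = _read_table(path, ["drug_id", "protein_id", "y_true", "y_pred"])
    out = []
    for row in rows:
        yt = None if row["y_true"] == "" else float(row["y_true"])
        out.append((row["drug_id"], row["protein_id"], yt, float(row["y_pred"])))
    return out


def pkd_from_kd_nm(kd_nm) -> np.ndarray:
    """Convert raw dissociation constants in nM to pKd = -log10(Kd * 1e-9).

    Opt-in converter following the community convention for kinase panels;
    the default pipeline passes labels through untransformed.
    """
    kd_nm = np.asarray(kd_nm, dtype=np.float64)
    if np.any(kd_nm <= 0):
        raise ValueError("Kd values must be positive")
    return -np.log10(kd_nm * 1e-9)
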