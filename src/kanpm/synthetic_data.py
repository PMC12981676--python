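"""Deterministic synthetic datasets emulating pretrained-model outputs.

Every downstream stage (graph construction, encoders, fusion, training,
metrics) is exercisable on a laptop with no downloads and no GPU: this module
fabricates residue embeddings (width 1152), drug token embeddings (width
384), contact-probability matrices with near-diagonal band plus sparse
long-range structure, small valid molecules, and affinity labels from a
planted latent-factor model

    affinity(d, p) = u_p . v_d + b + eps,   eps ~ N(0, noise_sd^2)

whose ground truth is returned for recovery tests.

The embedding stand-ins are unstructured Gaussians: they identify entities
but carry no biochemistry.  Synthetic runs therefore test *mechanism*
(shapes, gradients, ranking recovery of the planted signal), not benchmark
performance -- see docs/methods.md.

Seeding is hash-based per entity (never global-RNG-order-based), so the same
(id, seed) always yields the same record and adding entities never perturbs
existing ones.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .core_data import (
    AMINO_ACIDS,
    DRUG_EMBED_DIM,
    PROTEIN_EMBED_DIM,
    DrugRecord,
    InteractionRecord,
    ProteinRecord,
    write_matrix,
)
from .drug_featurizer import smiles_to_graph

__all__ = [
    "SyntheticConfig",
    "stable_seed",
    "gen_protein",
    "gen_drug",
    "gen_dataset",
    "write_dataset",
    "load_dataset",
    "DRUGLIKE_SMILES",
]


def stable_seed(*parts, base: int = 0) -> int:
    """Platform-stable 31-bit seed from a tuple of labels and a base seed."""
    key = "|".join(str(p) for p in parts) + f"|{base}"
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


#: ~50 valid drug-like molecules spanning 1..~30 heavy atoms
DRUGLIKE_SMILES = [
    "C", "CC", "CCO", "CC(=O)O", "CC(C)O", "CC(N)=O", "NCC(=O)O",
    "C1CCOC1", "CC(N)C(=O)O", "CCOC(=O)C", "OCC(O)CO", "C1CCNCC1",
    "c1ccccc1", "c1ccncc1", "C1CCCCC1", "Cc1ccccc1", "Oc1ccccc1",
    "Nc1ccccc1", "Brc1ccccc1", "Ic1ccccc1", "CCN(CC)CC", "ClC(Cl)Cl",
    "COc1ccccc1", "N#Cc1ccccc1", "O=C1CCCCC1", "O=C(O)CCC(=O)O",
    "CC(=O)c1ccccc1", "NC(=O)c1ccccc1", "c1ccc2[nH]ccc2c1",
    "O=[N+]([O-])c1ccccc1", "c1ccc2ccccc2c1", "OC(=O)c1ccccc1O",
    "CC(C)(C)c1ccccc1", "FC(F)(F)c1ccccc1", "CCCCCCCCCC",
    "CC1=CC(=O)CC(C)(C)C1", "O=S(=O)(N)c1ccccc1", "CC(=O)Nc1ccc(O)cc1",
    "NCCc1ccc(O)c(O)c1", "CN1CCC[C@H]1c1cccnc1", "c1ccc(-c2ccccc2)cc1",
    "N[C@@H](Cc1ccccc1)C(=O)O", "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O",
    "CC(=O)Oc1ccccc1C(=O)O", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "OC(c1ccccc1)c1ccccc1", "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "COc1ccc2cc(C(C)C(=O)O)ccc2c1", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "CC(C)NCC(O)COc1cccc2ccccc12", "O=C(O)Cc1ccccc1Nc1c(Cl)cccc1Cl",
    "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1",
    "O=C(O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O",
]

_HEAVY_COUNTS: list[int] | None = None


def _heavy_counts() -> list[int]:
    global _HEAVY_COUNTS
    if _HEAVY_COUNTS is None:
        from rdkit import Chem

        _HEAVY_COUNTS = [
            Chem.MolFromSmiles(smi).GetNumHeavyAtoms() for smi in DRUGLIKE_SMILES
        ]
    return _HEAVY_COUNTS


@dataclass
class SyntheticConfig:
    """Study conditions for a planted-signal synthetic dataset."""

    n_proteins: int = 40
    n_drugs: int = 40
    n_pairs: int = 1200
    protein_len_range: tuple = (40, 120)
    drug_atoms_range: tuple = (10, 30)
    embed_dim_protein: int = PROTEIN_EMBED_DIM
    embed_dim_drug: int = DRUG_EMBED_DIM
    contact_band_width: int = 3
    long_range_contact_prob: float = 0.02
    latent_dim: int = 4
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.protein_len_range
        if lo > hi or lo < 3:
            raise ValueError("protein_len_range must be a non-empty range, lo >= 3")
        lo, hi = self.drug_atoms_range
        if lo > hi or lo < 1:
            raise ValueError("drug_atoms_range must be a non-empty range, lo >= 1")
        if self.n_pairs > self.n_proteins * self.n_drugs:
            raise ValueError(
                f"n_pairs={self.n_pairs} exceeds the "
                f"{self.n_proteins}x{self.n_drugs} interaction grid"
            )
        if not (0.0 <= self.long_range_contact_prob <= 1.0):
            raise ValueError("long_range_contact_prob must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def gen_protein(length: int, seed: int, *,
                contact_band_width: int = 3,
                long_range_contact_prob: float = 0.02,
                embed_dim: int = PROTEIN_EMBED_DIM,
                protein_id: str | None = None) -> ProteinRecord:
    """Generate one synthetic protein record.

    The embedding matrix has shape ((length+2) x embed_dim) -- start and end
    special tokens included, provider flag set -- with entries drawn from a
    seeded standard normal scaled by 1/sqrt(embed_dim).  The contact matrix
    is symmetric with unit diagonal; entries within the near-diagonal band
    |i-j| <= contact_band_width exceed 0.5 (so the chain subgraph is always
    connected after thresholding), off-band entries exceed 0.5 with
    probability ``long_range_contact_prob``.
    """
    if length < 3:
        raise ValueError("protein length must be >= 3")
    rng = np.random.default_rng(stable_seed("protein", length, base=seed))
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    emb = rng.standard_normal((length + 2, embed_dim)) / np.sqrt(embed_dim)

    # upper triangle first, then mirror for exact symmetry
    M = rng.uniform(0.0, 0.45, size=(length, length))
    idx = np.arange(length)
    band = (np.abs(idx[:, None] - idx[None, :]) <= contact_band_width)
    M[band] = rng.uniform(0.55, 0.95, size=int(band.sum()))
    long_range = (~band) & (rng.random((length, length)) < long_range_contact_prob)
    M[long_range] = rng.uniform(0.55, 0.95, size=int(long_range.sum()))
    M = np.triu(M, 1)
    M = M + M.T
    np.fill_diagonal(M, 1.0)

    return ProteinRecord(
        protein_id=protein_id or f"synthP_{length}_{seed}",
        sequence=sequence,
        embeddings=emb,
        contact=M,
        has_special_tokens=True,
    )


def gen_drug(n_atoms: int, seed: int, *,
             embed_dim: int = DRUG_EMBED_DIM,
             drug_id: str | None = None) -> DrugRecord:
    """Generate one synthetic drug record.

    The SMILES is sampled from the packaged drug-like library filtered to
    molecules within 2 heavy atoms of ``n_atoms``; when none match, a simple
    alkane/alcohol chain with exactly ``n_atoms`` heavy atoms is used
    instead (always valid).  Token embeddings (one token per SMILES
    character, no special tokens) are seeded from (smiles, seed).
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(stable_seed("drug", n_atoms, base=seed))
    counts = _heavy_counts()
    candidates = [s for s, c in zip(DRUGLIKE_SMILES, counts)
                  if abs(c - n_atoms) <= 2]
    if n_atoms == 1:
        smiles = "C"
    elif candidates:
        smiles = candidates[int(rng.integers(len(candidates)))]
    elif rng.random() < 0.5 or n_atoms < 2:
        smiles = "C" * n_atoms
    else:
        smiles = "C" * (n_atoms - 1) + "O"

    emb_rng = np.random.default_rng(stable_seed("drug-emb", smiles, base=seed))
    emb = emb_rng.standard_normal((len(smiles), embed_dim)) / np.sqrt(embed_dim)
    return DrugRecord(
        drug_id=drug_id or f"synthD_{n_atoms}_{seed}",
        smiles=smiles,
        embeddings=emb,
        graph=smiles_to_graph(smiles),
    )


def gen_dataset(cfg: SyntheticConfig):
    """Generate a full synthetic dataset.

    Returns ``(proteins, drugs, interactions, latent_truth)`` where
    ``latent_truth`` holds the per-entity latent vectors, the global bias
    and the realized noise standard deviation for recovery assertions.
    """
    proteins: list[ProteinRecord] = []
    drugs: list[DrugRecord] = []

    for i in range(cfg.n_proteins):
        pid = f"p{i:04d}"
        rng = np.random.default_rng(stable_seed("plen", pid, base=cfg.seed))
        length = int(rng.integers(cfg.protein_len_range[0],
                                  cfg.protein_len_range[1] + 1))
        rec = gen_protein(
            length, stable_seed(pid, base=cfg.seed),
            contact_band_width=cfg.contact_band_width,
            long_range_contact_prob=cfg.long_range_contact_prob,
            embed_dim=cfg.embed_dim_protein,
            protein_id=pid,
        )
        proteins.append(rec)

    for i in range(cfg.n_drugs):
        did = f"d{i:04d}"
        rng = np.random.default_rng(stable_seed("datoms", did, base=cfg.seed))
        n_atoms = int(rng.integers(cfg.drug_atoms_range[0],
                                   cfg.drug_atoms_range[1] + 1))
        rec = gen_drug(
            n_atoms, stable_seed(did, base=cfg.seed),
            embed_dim=cfg.embed_dim_drug,
            drug_id=did,
        )
        drugs.append(rec)

    # planted latent factors
    u = {p.protein_id: np.random.default_rng(
            stable_seed("latent-p", p.protein_id, base=cfg.seed)
         ).standard_normal(cfg.latent_dim) for p in proteins}
    v = {d.drug_id: np.random.default_rng(
            stable_seed("latent-d", d.drug_id, base=cfg.seed)
         ).standard_normal(cfg.latent_dim) for d in drugs}
    bias = float(np.random.default_rng(
        stable_seed("bias", base=cfg.seed)).standard_normal())

    grid = cfg.n_proteins * cfg.n_drugs
    pair_rng = np.random.default_rng(stable_seed("pairs", base=cfg.seed))
    chosen = pair_rng.choice(grid, size=cfg.n_pairs, replace=False)
    interactions = []
    for k in np.sort(chosen):
        pi, di = divmod(int(k), cfg.n_drugs)
        pid, did = proteins[pi].protein_id, drugs[di].drug_id
        noise_rng = np.random.default_rng(
            stable_seed("noise", did, pid, base=cfg.seed))
        eps = cfg.noise_sd * noise_rng.standard_normal()
        y = float(u[pid] @ v[did] + bias + eps)
        interactions.append(InteractionRecord(did, pid, y))

    latent_truth = {
        "protein_latents": u,
        "drug_latents": v,
        "bias": bias,
        "noise_sd": cfg.noise_sd,
    }
    return proteins, drugs, interactions, latent_truth


# ---------------------------------------------------------------------------
# on-disk round trip (core_data formats)
# ---------------------------------------------------------------------------

def write_dataset(out_dir, proteins: Iterable[ProteinRecord],
                  drugs: Iterable[DrugRecord],
                  interactions: Iterable[InteractionRecord]):
    """Write a dataset directory: proteins.fasta, drugs.csv,
    interactions.csv and per-entity matrices under matrices/."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mats = out / "matrices"
    mats.mkdir(exist_ok=True)

    with open(out / "proteins.fasta", "w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")
            write_matrix(mats / f"{p.protein_id}_embeddings.npy", p.embeddings)
            write_matrix(mats / f"{p.protein_id}_contact.npy", p.contact)

    with open(out / "drugs.csv", "w") as fh:
        fh.write("drug_id,smiles\n")
        for d in drugs:
            fh.write(f"{d.drug_id},{d.smiles}\n")
            write_matrix(mats / f"{d.drug_id}_embeddings.npy", d.embeddings)

    with open(out / "interactions.csv", "w") as fh:
        fh.write("drug_id,protein_id,affinity\n")
        for r in interactions:
            fh.write(f"{r.drug_id},{r.protein_id},{r.affinity:.10g}\n")


def load_dataset(data_dir, has_special_tokens: bool = True):
    """Load a dataset directory written by :func:`write_dataset`."""
    from .core_data import read_drug_table, read_fasta, read_interaction_table, read_matrix

    data = Path(data_dir)
    mats = data / "matrices"
    proteins = []
    for pid, seq in read_fasta(data / "proteins.fasta"):
        proteins.append(ProteinRecord(
            pid, seq,
            read_matrix(mats / f"{pid}_embeddings.npy"),
            read_matrix(mats / f"{pid}_contact.npy"),
            has_special_tokens=has_special_tokens,
        ))
    drugs = []
    for did, smiles in read_drug_table(data / "drugs.csv"):
        drugs.append(DrugRecord(
            did, smiles,
            read_matrix(mats / f"{did}_embeddings.npy"),
            graph=smiles_to_graph(smiles),
        ))
    interactions = read_interaction_table(data / "interactions.csv")
    return proteins, drugs, interactions
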