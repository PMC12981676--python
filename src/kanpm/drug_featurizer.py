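"""SMILES -> weighted molecular graph featurization.

Each heavy atom becomes a node carrying an 88-dimensional feature vector
(one-hot blocks for element, degree, formal charge, hybridization, total
hydrogen count, plus aromaticity, ring membership and chirality); each bond
contributes both directed arcs weighted by its bond order (single 1.0,
double 2.0, triple 3.0, aromatic 1.5).

The 88-d block layout is this package's own composition of the standard
property families; it is versioned through :class:`AtomFeatureScheme` so an
alternative layout can be swapped in without touching the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .core_data import WeightedGraph

__all__ = [
    "AtomFeatureScheme",
    "DEFAULT_SCHEME",
    "smiles_to_graph",
    "pad_drug_batch",
    "tanimoto_similarity",
]

# 43 element symbols; anything else hits the trailing OTHER bucket
_ELEMENTS = [
    "C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B",
    "Si", "Se", "Te", "As", "Al", "Zn", "Ca", "Na", "K", "Mg",
    "Fe", "Cu", "Mn", "Co", "Ni", "Cr", "Mo", "V", "Li", "Ba",
    "Sr", "Sn", "Sb", "Bi", "Pt", "Au", "Ag", "Hg", "Pd", "Cd",
    "Ti", "Zr", "W",
]

_HYBRIDIZATIONS = ["S", "SP", "SP2", "SP3", "SP3D", "SP3D2", "UNSPECIFIED"]


@dataclass
class AtomFeatureScheme:
    """Block layout of the per-atom feature vector (widths sum to 88)."""

    element_vocab: list = field(default_factory=lambda: list(_ELEMENTS))
    degree_max: int = 10          # one-hot 0..10          -> 11
    charge_range: tuple = (-5, 5)  # one-hot -5..+5        -> 11
    hybridizations: list = field(default_factory=lambda: list(_HYBRIDIZATIONS))
    total_h_max: int = 8          # one-hot 0..8           -> 9

    @property
    def width(self) -> int:
        return (
            len(self.element_vocab) + 1        # + OTHER           -> 44
            + self.degree_max + 1              #                   -> 11
            + self.charge_range[1] - self.charge_range[0] + 1      # 11
            + len(self.hybridizations) + 1     # + OTHER           -> 8
            + self.total_h_max + 1             #                   -> 9
            + 1 + 1 + 3                        # aromatic, ring, chirality
        )


DEFAULT_SCHEME = AtomFeatureScheme()
assert DEFAULT_SCHEME.width == 88


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[index] = 1.0
    return v


def _atom_features(atom: Chem.Atom, scheme: AtomFeatureScheme) -> np.ndarray:
    blocks = []
    # element (out-of-vocabulary -> OTHER, never an error)
    vocab = scheme.element_vocab
    try:
        idx = vocab.index(atom.GetSymbol())
    except ValueError:
        idx = len(vocab)
    blocks.append(_one_hot(idx, len(vocab) + 1))
    # degree (heavy-atom connections), clamped into the one-hot range
    blocks.append(_one_hot(min(atom.GetDegree(), scheme.degree_max),
                           scheme.degree_max + 1))
    # formal charge
    lo, hi = scheme.charge_range
    charge = int(np.clip(atom.GetFormalCharge(), lo, hi))
    blocks.append(_one_hot(charge - lo, hi - lo + 1))
    # hybridization (OTHER bucket for exotic states)
    hyb = str(atom.GetHybridization())
    try:
        hidx = scheme.hybridizations.index(hyb)
    except ValueError:
        hidx = len(scheme.hybridizations)
    blocks.append(_one_hot(hidx, len(scheme.hybridizations) + 1))
    # total hydrogens (implicit + explicit)
    blocks.append(_one_hot(min(atom.GetTotalNumHs(), scheme.total_h_max),
                           scheme.total_h_max + 1))
    blocks.append(np.array([1.0 if atom.GetIsAromatic() else 0.0]))
    blocks.append(np.array([1.0 if atom.IsInRing() else 0.0]))
    # CIP chirality: none / R / S
    cip = atom.GetPropsAsDict().get("_CIPCode", None)
    blocks.append(_one_hot({None: 0, "R": 1, "S": 2}.get(cip, 0), 3))
    return np.concatenate(blocks)


def smiles_to_graph(smiles: str,
                    scheme: AtomFeatureScheme = DEFAULT_SCHEME,
                    kekulize: bool = False) -> WeightedGraph:
    """Parse a SMILES string into a weighted molecular graph.

    With ``kekulize=False`` (default) aromatic bonds carry order 1.5;
    ``kekulize=True`` uses alternating single/double Kekule orders instead.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    if mol.GetNumHeavyAtoms() < 1:
        raise ValueError(f"SMILES has no heavy atoms: {smiles!r}")
    if kekulize:
        mol = Chem.Mol(mol)
        Chem.Kekulize(mol, clearAromaticFlags=True)
    Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    feats = np.stack([_atom_features(a, scheme) for a in mol.GetAtoms()])
    edges, weights = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        w = bond.GetBondTypeAsDouble()
        edges.extend([(i, j), (j, i)])
        weights.extend([w, w])
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    weights = np.asarray(weights, dtype=np.float64)
    return WeightedGraph(feats, edges, weights)


def pad_drug_batch(items, cap: int = 220):
    """Pad a batch of per-drug token matrices to a common length.

    Returns ``(batch, mask)`` where ``batch`` has shape
    (B, min(max length, cap), dim) and the boolean ``mask`` marks real
    tokens; sequences longer than ``cap`` are truncated.
    """
    from .protein_featurizer import pad_token_batch

    return pad_token_batch(items, cap)


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def tanimoto_similarity(smiles_a: str, smiles_b: str) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B| over Morgan fingerprint bit sets
    (radius 2, 2048 bits); used to audit train/test chemical leakage."""
    mols = []
    for smi in (smiles_a, smiles_b):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        mols.append(mol)
    fa, fb = (_MORGAN.GetFingerprint(m) for m in mols)
    a = set(fa.GetOnBits())
    b = set(fb.GetOnBits())
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)
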