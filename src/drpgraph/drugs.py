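"""SMILES parsing, molecular graphs and the drug graph-convolution encoder.

A drug enters as a SMILES string, becomes an atom-level graph (one-hot
element/degree/H-count features, aromaticity, formal charge; symmetric
bond adjacency) and leaves as an F-dimensional embedding produced by two
rounds of symmetric-normalized neighborhood aggregation with self-loops
followed by a mean readout — so the embedding is invariant to atom
relabeling by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, DataStructs

from .autodiff import Tensor, concat
from .nn import Linear, Module

RDLogger.DisableLog("rdApp.*")

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
MAX_DEGREE = 5
MAX_H = 4
#: element one-hot (+other) + degree one-hot + aromatic + formal charge + H one-hot
ATOM_FEATURE_WIDTH = (len(ELEMENTS) + 1) + (MAX_DEGREE + 1) + 1 + 1 + (MAX_H + 1)


@dataclass
class MolecularGraph:
    """Atom-node attribute matrix and bond adjacency for one drug."""

    drug_id: str
    atom_features: np.ndarray   # (N_d, ATOM_FEATURE_WIDTH)
    bond_adjacency: np.ndarray  # (N_d, N_d) binary, symmetric, zero diagonal
    bond_types: np.ndarray      # (N_d, N_d) rdkit bond-type codes alongside
    n_fragments: int = 1

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]


def _atom_features(atom: Chem.Atom) -> np.ndarray:
    vec = np.zeros(ATOM_FEATURE_WIDTH)
    sym = atom.GetSymbol()
    vec[ELEMENTS.index(sym) if sym in ELEMENTS else len(ELEMENTS)] = 1.0
    off = len(ELEMENTS) + 1
    vec[off + min(atom.GetDegree(), MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    vec[off] = float(atom.GetIsAromatic())
    vec[off + 1] = float(atom.GetFormalCharge())
    vec[off + 2 + min(atom.GetTotalNumHs(), MAX_H)] = 1.0
    return vec


def smiles_to_graph(smiles: str, drug_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Hydrogens stay implicit and atoms follow the parser's canonical order.
    Multi-fragment inputs (salts) are reduced to the largest fragment with
    a warning. Unparseable strings raise ``ValueError`` carrying the input.
    """
    if not smiles:
        raise ValueError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True)
    n_fragments = len(frags)
    if n_fragments > 1:
        warnings.warn(f"SMILES {smiles!r} has {n_fragments} fragments; using the largest")
        mol = max(frags, key=lambda m: m.GetNumAtoms())
    n = mol.GetNumAtoms()
    feats = np.stack([_atom_features(a) for a in mol.GetAtoms()])
    adj = np.zeros((n, n))
    btypes = np.zeros((n, n))
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adj[i, j] = adj[j, i] = 1.0
        btypes[i, j] = btypes[j, i] = float(bond.GetBondTypeAsDouble())
    return MolecularGraph(drug_id=drug_id or smiles, atom_features=feats,
                          bond_adjacency=adj, bond_types=btypes,
                          n_fragments=n_fragments)


def morgan_fingerprints(smiles_list: list[str], n_bits: int = 2048,
                        radius: int = 2) -> np.ndarray:
    """Hashed circular (Morgan) fingerprints as a binary matrix."""
    gen = AllChem.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = np.zeros((len(smiles_list), n_bits))
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        arr = np.zeros(n_bits, dtype=np.int8)
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(mol), arr)
        out[i] = arr
    return out


def _normalized_adjacency(adj: np.ndarray) -> np.ndarray:
    """Symmetric normalization with self-loops: D^-1/2 (A+I) D^-1/2."""
    a = adj + np.eye(adj.shape[0])
    d = a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return a * inv_sqrt[:, None] * inv_sqrt[None, :]


class DrugEncoder(Module):
    """Two-layer graph convolution with mean readout and a linear head to F."""

    def __init__(self, f_dim: int, rng: np.random.Generator, hidden: int = 64):
        self.lin1 = Linear(ATOM_FEATURE_WIDTH, hidden, rng)
        self.lin2 = Linear(hidden, hidden, rng)
        self.head = Linear(hidden, f_dim, rng)

    def encode_one(self, graph: MolecularGraph) -> Tensor:
        a_norm = _normalized_adjacency(graph.bond_adjacency)
        x = Tensor(graph.atom_features)
        h = (Tensor(a_norm) @ self.lin1(x)).relu()
        h = (Tensor(a_norm) @ self.lin2(h)).relu()
        pooled = h.mean(axis=0, keepdims=True)  # permutation-invariant readout
        return self.head(pooled)

    def __call__(self, graphs: list[MolecularGraph]) -> Tensor:
        if not graphs:
            raise ValueError("no molecular graphs to encode")
        return concat([self.encode_one(g) for g in graphs], axis=0)


def encode_drugs(graphs: list[MolecularGraph], encoder: DrugEncoder) -> np.ndarray:
    """Convenience: encode and return plain (N_D, F) ndarray."""
    return encoder(graphs).data
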