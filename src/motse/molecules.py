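"""Molecular graph data model, SMILES parsing, and atom featurization.

Molecules are heavy-atom graphs: nodes carry element, formal charge,
implicit-hydrogen count and an aromaticity flag; edges carry a bond order.
Hydrogens are never explicit atoms. The atom order fixed at parse (or
generation) time is canonical and must be preserved through featurization,
encoding and attribution, because attribution vectors of different task
models are compared position-wise on the same molecule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "Atom",
    "MolecularGraph",
    "ParseError",
    "parse_smiles",
    "featurize",
    "graph_to_dict",
    "graph_from_dict",
    "graphs_to_json",
    "graphs_from_json",
    "FEATURE_SCHEMA_ID",
    "N_FEATURES",
]

# Default featurization schema: one-hot element (9 symbols + other),
# one-hot heavy degree 0-5, one-hot attached-H count 0-4, formal charge,
# aromatic flag. 10 + 6 + 5 + 1 + 1 = 23 features.
FEATURE_SCHEMA_ID = "onehot-v1"
_ELEMENT_VOCAB = ["C", "N", "O", "F", "S", "Cl", "Br", "I", "P"]
_MAX_DEGREE = 5
_MAX_H = 4
N_FEATURES = (len(_ELEMENT_VOCAB) + 1) + (_MAX_DEGREE + 1) + (_MAX_H + 1) + 2


class ParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""


@dataclass(frozen=True)
class Atom:
    element: str
    formal_charge: int = 0
    n_attached_H: int = 0
    aromatic: bool = False


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with typed bonds.

    ``bonds`` entries are (i, j, order) with 0-based atom indices and order
    in {1.0, 2.0, 3.0, 1.5}; 1.5 encodes an aromatic bond. The graph is
    undirected; each unordered pair appears once.
    """

    atoms: List[Atom]
    bonds: List[Tuple[int, int, float]]
    source_id: str = ""

    def __post_init__(self):
        n = len(self.atoms)
        seen = set()
        for i, j, order in self.bonds:
            if i == j:
                raise ValueError(f"self-bond on atom {i} in {self.source_id!r}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond index out of range in {self.source_id!r}")
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate bond {key} in {self.source_id!r}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degrees(self) -> np.ndarray:
        """Heavy-atom degree of every atom."""
        deg = np.zeros(self.n_atoms, dtype=np.intp)
        for i, j, _ in self.bonds:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, k: int) -> List[Tuple[int, float]]:
        out = []
        for i, j, order in self.bonds:
            if i == k:
                out.append((j, order))
            elif j == k:
                out.append((i, order))
        return out


def parse_smiles(s: str, source_id: str | None = None) -> MolecularGraph:
    """Parse a SMILES string into a heavy-atom graph (RDKit order kept)."""
    from rdkit import Chem

    if not s or not s.strip():
        raise ParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(s)
    if mol is None:
        raise ParseError(f"unparsable SMILES: {s!r}")
    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            n_attached_H=a.GetTotalNumHs(),
            aromatic=a.GetIsAromatic(),
        )
        for a in mol.GetAtoms()
    ]
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), float(b.GetBondTypeAsDouble()))
        for b in mol.GetBonds()
    ]
    return MolecularGraph(atoms=atoms, bonds=bonds, source_id=source_id if source_id is not None else s)


def featurize(g: MolecularGraph, schema: str = FEATURE_SCHEMA_ID) -> np.ndarray:
    """Atom feature matrix (n_atoms x 23) under the default one-hot schema.

    Elements outside the vocabulary map to the trailing "other" slot;
    degrees and H counts are clipped into their one-hot range, so the
    featurization is total.
    """
    if schema != FEATURE_SCHEMA_ID:
        raise ValueError(f"unknown featurization schema {schema!r}")
    n = g.n_atoms
    X = np.zeros((n, N_FEATURES), dtype=np.float64)
    deg = g.degrees()
    elem_index = {e: k for k, e in enumerate(_ELEMENT_VOCAB)}
    off_deg = len(_ELEMENT_VOCAB) + 1
    off_h = off_deg + _MAX_DEGREE + 1
    off_charge = off_h + _MAX_H + 1
    for k, atom in enumerate(g.atoms):
        X[k, elem_index.get(atom.element, len(_ELEMENT_VOCAB))] = 1.0
        X[k, off_deg + min(int(deg[k]), _MAX_DEGREE)] = 1.0
        X[k, off_h + min(atom.n_attached_H, _MAX_H)] = 1.0
        X[k, off_charge] = float(atom.formal_charge)
        X[k, off_charge + 1] = 1.0 if atom.aromatic else 0.0
    return X


# ---------------------------------------------------------------------------
# JSON graph dialect — the interchange format of record
# ---------------------------------------------------------------------------

def graph_to_dict(g: MolecularGraph) -> dict:
    return {
        "source_id": g.source_id,
        "atoms": [
            {"element": a.element, "charge": a.formal_charge, "nH": a.n_attached_H,
             "aromatic": bool(a.aromatic)}
            for a in g.atoms
        ],
        "bonds": [{"i": i, "j": j, "order": order} for i, j, order in g.bonds],
    }


def graph_from_dict(d: dict) -> MolecularGraph:
    atoms = [
        Atom(a["element"], int(a.get("charge", 0)), int(a.get("nH", 0)),
             bool(a.get("aromatic", False)))
        for a in d["atoms"]
    ]
    bonds = [(int(b["i"]), int(b["j"]), float(b["order"])) for b in d["bonds"]]
    return MolecularGraph(atoms=atoms, bonds=bonds, source_id=str(d.get("source_id", "")))


def graphs_to_json(graphs: Iterable[MolecularGraph]) -> str:
    return json.dumps([graph_to_dict(g) for g in graphs], indent=None, sort_keys=True)


def graphs_from_json(text: str) -> List[MolecularGraph]:
    return [graph_from_dict(d) for d in json.loads(text)]


def molecules_hash(graphs: Sequence[MolecularGraph]) -> str:
    """Order-sensitive content hash of a molecule list (probe identity)."""
    payload = graphs_to_json(graphs).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
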