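"""Synthetic molecular graphs labeled with four counting tasks.

The generator grows connected, valence-valid heavy-atom graphs and labels
them with four Lipinski-style descriptors — NOCount, NHOHCount, NHD
(hydrogen-bond donors) and NHA (hydrogen-bond acceptors) — giving a
benchmark whose ground-truth task relationships are known from chemistry:
donors are the H-carrying subset of N/O atoms, so NHD tracks NHOHCount more
closely than NOCount, while acceptors include H-free N/O atoms, so NHA
tracks NOCount more closely than NHOHCount.

Generation: a random spanning tree is grown atom by atom under residual
valence constraints, then a few ring-closing bonds are added where both
endpoints still have free valence. Attached hydrogens are implicit
(valence minus heavy-bond order sum); bond orders are 1 or 2 only, no
aromaticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Tuple

import numpy as np

from .datasets import TaskDataset, random_split
from .molecules import Atom, MolecularGraph

__all__ = [
    "GeneratorConfig",
    "ConfigurationError",
    "generate_molecules",
    "label_NOCount",
    "label_NHOHCount",
    "label_NHD",
    "label_NHA",
    "PROPERTY_RULES",
    "build_benchmark",
]

DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "S": 2}


class ConfigurationError(ValueError):
    """Raised for an invalid generator configuration."""


@dataclass
class GeneratorConfig:
    element_alphabet: Tuple[str, ...] = ("C", "N", "O", "F", "S")
    valence_table: Dict[str, int] = field(default_factory=lambda: dict(DEFAULT_VALENCE))
    n_heavy_atoms_range: Tuple[int, int] = (4, 14)
    bond_order_probs: Dict[int, float] = field(default_factory=lambda: {1: 0.85, 2: 0.15})
    seed: int = 0

    def __post_init__(self):
        missing = [e for e in self.element_alphabet if e not in self.valence_table]
        if missing:
            raise ConfigurationError(f"valence table missing elements: {missing}")
        if any(v < 1 for v in self.valence_table.values()):
            raise ConfigurationError("valences must be >= 1")
        lo, hi = self.n_heavy_atoms_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("n_heavy_atoms_range lower bound must be >= 2")
        if set(self.bond_order_probs) - {1, 2}:
            raise ConfigurationError("bond orders are restricted to {1, 2}")
        total = sum(self.bond_order_probs.values())
        if total <= 0:
            raise ConfigurationError("bond_order_probs must have positive mass")
        self.bond_order_probs = {k: v / total for k, v in self.bond_order_probs.items()}


def _grow_molecule(cfg: GeneratorConfig, rng: np.random.Generator, index: int) -> MolecularGraph:
    lo, hi = cfg.n_heavy_atoms_range
    alphabet = list(cfg.element_alphabet)
    orders = sorted(cfg.bond_order_probs)
    order_p = np.array([cfg.bond_order_probs[o] for o in orders])
    for _attempt in range(100):
        n_target = int(rng.integers(lo, hi + 1))
        elements = [alphabet[rng.integers(len(alphabet))]]
        residual = [cfg.valence_table[elements[0]]]
        bonds: List[Tuple[int, int, float]] = []
        ok = True
        for _ in range(n_target - 1):
            open_atoms = [k for k, r in enumerate(residual) if r >= 1]
            if not open_atoms:
                ok = False
                break
            parent = open_atoms[rng.integers(len(open_atoms))]
            elem = alphabet[rng.integers(len(alphabet))]
            val = cfg.valence_table[elem]
            feasible = [o for o in orders if o <= residual[parent] and o <= val]
            p = np.array([cfg.bond_order_probs[o] for o in feasible])
            order = int(rng.choice(feasible, p=p / p.sum()))
            k = len(elements)
            elements.append(elem)
            residual.append(val - order)
            residual[parent] -= order
            bonds.append((parent, k, float(order)))
        if not ok:
            continue  # deterministic retry on a dead-end growth
        n = len(elements)
        # ring closures between non-adjacent open atoms
        bonded = {(min(i, j), max(i, j)) for i, j, _ in bonds}
        for _ in range(n // 4):
            open_atoms = [k for k, r in enumerate(residual) if r >= 1]
            if len(open_atoms) < 2:
                break
            i, j = rng.choice(open_atoms, size=2, replace=False)
            i, j = int(min(i, j)), int(max(i, j))
            if (i, j) in bonded:
                continue
            feasible = [o for o in orders if o <= residual[i] and o <= residual[j]]
            if not feasible:
                continue
            p = np.array([cfg.bond_order_probs[o] for o in feasible])
            order = int(rng.choice(feasible, p=p / p.sum()))
            bonds.append((i, j, float(order)))
            bonded.add((i, j))
            residual[i] -= order
            residual[j] -= order
        atoms = [
            Atom(element=e, formal_charge=0, n_attached_H=int(r), aromatic=False)
            for e, r in zip(elements, residual)
        ]
        return MolecularGraph(atoms=atoms, bonds=bonds, source_id=f"synth-{cfg.seed}-{index}")
    raise ConfigurationError("could not grow a valence-valid molecule (config too tight)")


def generate_molecules(cfg: GeneratorConfig, n: int) -> List[MolecularGraph]:
    """Generate ``n`` connected, valence-valid molecular graphs (seeded)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    return [_grow_molecule(cfg, rng, k) for k in range(n)]


# ---------------------------------------------------------------------------
# Property rules
# ---------------------------------------------------------------------------

def label_NOCount(g: MolecularGraph) -> int:
    """Number of nitrogen and oxygen atoms."""
    return sum(1 for a in g.atoms if a.element in ("N", "O"))


def label_NHOHCount(g: MolecularGraph) -> int:
    """Total hydrogens attached to N and O atoms (an NH2 contributes 2)."""
    return sum(a.n_attached_H for a in g.atoms if a.element in ("N", "O"))


def label_NHD(g: MolecularGraph) -> int:
    """Hydrogen-bond donors: N/O atoms carrying at least one H."""
    return sum(1 for a in g.atoms if a.element in ("N", "O") and a.n_attached_H >= 1)


def label_NHA(g: MolecularGraph) -> int:
    """Hydrogen-bond acceptors: N/O atoms, excluding N double-bonded to O.

    The nitro-like exclusion keeps NHA close to, but not identical with,
    NOCount, mirroring the chemical fact that some nitrogens are too
    electron-poor to accept.
    """
    count = 0
    for k, a in enumerate(g.atoms):
        if a.element not in ("N", "O"):
            continue
        if a.element == "N":
            excluded = any(
                order == 2.0 and g.atoms[j].element == "O" for j, order in g.neighbors(k)
            )
            if excluded:
                continue
        count += 1
    return count


PROPERTY_RULES: Dict[str, Callable[[MolecularGraph], int]] = {
    "NOCount": label_NOCount,
    "NHOHCount": label_NHOHCount,
    "NHD": label_NHD,
    "NHA": label_NHA,
}


def build_benchmark(cfg: GeneratorConfig, n: int) -> Dict[str, TaskDataset]:
    """Four regression TaskDatasets over one shared molecule list and split."""
    if n < 100:
        raise ValueError("benchmark needs n >= 100 molecules")
    molecules = generate_molecules(cfg, n)
    splits = random_split(n, seed=cfg.seed)
    out: Dict[str, TaskDataset] = {}
    for name, rule in PROPERTY_RULES.items():
        labels = np.array([float(rule(g)) for g in molecules])
        out[name] = TaskDataset(
            task_id=name,
            task_type="regression",
            molecules=molecules,
            labels=labels,
            splits=splits.copy(),
        )
    return out
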