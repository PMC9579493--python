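"""Local task knowledge: per-atom Gradient*Input attribution.

For a molecule with atom feature matrix U (|V| x Nd) and model output
y (the z-scored regression value or the classification logit), the
importance score of atom k is

    a_k = (1/Nd) * sum_f  U[k, f] * dy/dU[k, f]

— a first-order estimate of how much the output would change if atom k's
features were zeroed. The scores over a shared probe set form the "local"
embedding of a task; tasks that care about the same atoms for the same
molecules are close in this space.

Gradients are exact (reverse-mode), taken with the feature matrix as the
free input and the model in inference mode; one-hot features are treated
as continuous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .autodiff import Tensor
from .datasets import ProbeSet
from .model import TaskModel, build_batch, prepare_graph
from .molecules import MolecularGraph

__all__ = [
    "AttributionVector",
    "AttributionSet",
    "AttributionError",
    "grad_x_input",
    "attribution_set",
    "render_attribution",
]


class AttributionError(RuntimeError):
    """Raised on non-finite gradients or misaligned score vectors."""


@dataclass
class AttributionVector:
    """Per-atom importance scores aligned to one molecule's atom order."""

    scores: np.ndarray
    molecule_ref: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if not np.isfinite(self.scores).all():
            raise AttributionError(f"non-finite attribution for {self.molecule_ref!r}")

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class AttributionSet:
    """One attribution vector per probe molecule, in probe order."""

    vectors: List[AttributionVector]
    task_id: str
    probe_hash: str

    def __len__(self) -> int:
        return len(self.vectors)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task_id": self.task_id,
                "probe_hash": self.probe_hash,
                "scores": [v.scores.tolist() for v in self.vectors],
                "refs": [v.molecule_ref for v in self.vectors],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AttributionSet":
        d = json.loads(text)
        vectors = [
            AttributionVector(np.asarray(s), ref)
            for s, ref in zip(d["scores"], d["refs"])
        ]
        return cls(vectors=vectors, task_id=d["task_id"], probe_hash=d["probe_hash"])


def _attribute_batch(model: TaskModel, graphs: Sequence[MolecularGraph]) -> List[np.ndarray]:
    """Gradient*Input scores for a batch (graphs are independent, so the
    gradient of the summed output gives each molecule's own gradient)."""
    prepped = [prepare_graph(g) for g in graphs]
    X, A, offsets = build_batch(prepped)
    xt = Tensor(X, requires_grad=True)
    out = model.output_tensor(xt, A, offsets)
    from .autodiff import total_sum

    total_sum(out).backward()
    grad = xt.grad
    if grad is None or not np.isfinite(grad).all():
        raise AttributionError("non-finite gradient over the batch")
    contrib = X * grad  # elementwise Gradient*Input
    per_atom = contrib.mean(axis=1)  # average over the Nd feature dimensions
    bounds = np.append(offsets, X.shape[0])
    return [per_atom[lo:hi] for lo, hi in zip(bounds[:-1], bounds[1:])]


def grad_x_input(model: TaskModel, g: MolecularGraph) -> AttributionVector:
    """Per-atom Gradient*Input scores for one molecule."""
    try:
        scores = _attribute_batch(model, [g])[0]
    except AttributionError as err:
        raise AttributionError(f"{err} (molecule {g.source_id!r})") from err
    return AttributionVector(scores=scores, molecule_ref=g.source_id)


def attribution_set(
    model: TaskModel, probe: ProbeSet, batch_size: int = 128
) -> AttributionSet:
    """Attribution vectors for every probe molecule, in probe order."""
    vectors: List[AttributionVector] = []
    mols = probe.molecules
    for k in range(0, len(mols), batch_size):
        chunk = mols[k : k + batch_size]
        try:
            scores = _attribute_batch(model, chunk)
        except AttributionError as err:
            raise AttributionError(f"{err} (probe molecules {k}..{k + len(chunk) - 1})") from err
        vectors.extend(
            AttributionVector(s, g.source_id) for s, g in zip(scores, chunk)
        )
    return AttributionSet(vectors=vectors, task_id=model.task_id, probe_hash=probe.hash)


def render_attribution(g: MolecularGraph, A: AttributionVector) -> List[dict]:
    """Per-atom table for visualization, with min-max normalized scores.

    A constant score vector normalizes to 0.5 everywhere.
    """
    if len(A) != g.n_atoms:
        raise AttributionError(
            f"attribution length {len(A)} != {g.n_atoms} atoms of {g.source_id!r}"
        )
    lo, hi = float(A.scores.min()), float(A.scores.max())
    if hi - lo < 1e-300:
        norm = np.full(len(A), 0.5)
    else:
        norm = (A.scores - lo) / (hi - lo)
    return [
        {
            "index": k,
            "element": g.atoms[k].element,
            "score": float(A.scores[k]),
            "normalized": float(norm[k]),
        }
        for k in range(g.n_atoms)
    ]
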