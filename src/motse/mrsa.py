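"""Global task knowledge: molecular representation similarity analysis.

A task model's encoder maps every probe molecule to a latent vector;
stacking these gives the representation matrix Z (Np x d_enc). The task is
then characterized not by Z itself (which lives in a model-specific basis)
but by the pairwise Pearson correlations between probe molecules'
representations:

    r_{m,n} = pearson(z_m, z_n),   1 <= m < n <= Np,

flattened in row-major upper-triangle order into a correlation vector of
length Np(Np-1)/2. Two tasks whose encoders induce similar geometric
relationships among the same probe molecules get similar correlation
vectors, whatever their internal coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .datasets import ProbeSet
from .model import TaskModel

__all__ = [
    "RepresentationMatrix",
    "CorrelationVector",
    "DegenerateRepresentationError",
    "embed_probe",
    "pearson",
    "correlation_vector",
]

VARIANCE_TOL = 1e-12


class DegenerateRepresentationError(ValueError):
    """Raised when a representation (or input vector) has ~zero variance."""


@dataclass
class RepresentationMatrix:
    Z: np.ndarray  # (Np, d_enc), rows aligned to probe order
    task_id: str
    probe_hash: str

    def __post_init__(self):
        self.Z = np.asarray(self.Z, dtype=np.float64)
        if self.Z.ndim != 2:
            raise ValueError("representation matrix must be 2-D")
        if not np.isfinite(self.Z).all():
            raise ValueError(f"non-finite representation for task {self.task_id!r}")

    @property
    def n_probe(self) -> int:
        return self.Z.shape[0]


@dataclass
class CorrelationVector:
    values: np.ndarray  # length Np(Np-1)/2, upper-triangle row-major
    task_id: str
    probe_hash: str
    n_probe: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        expect = self.n_probe * (self.n_probe - 1) // 2
        if len(self.values) != expect:
            raise ValueError(f"correlation vector length {len(self.values)} != {expect}")
        if not ((self.values >= -1.0 - 1e-12) & (self.values <= 1.0 + 1e-12)).all():
            raise ValueError("correlation values outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def to_json(self) -> str:
        return json.dumps(
            {
                "task_id": self.task_id,
                "probe_hash": self.probe_hash,
                "n_probe": self.n_probe,
                "values": self.values.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CorrelationVector":
        d = json.loads(text)
        return cls(
            values=np.asarray(d["values"]),
            task_id=d["task_id"],
            probe_hash=d["probe_hash"],
            n_probe=int(d["n_probe"]),
        )


def embed_probe(model: TaskModel, probe: ProbeSet, batch_size: int = 256) -> RepresentationMatrix:
    """Encoder representations of every probe molecule, in probe order."""
    rows = [
        model.encode(probe.molecules[k : k + batch_size])
        for k in range(0, len(probe), batch_size)
    ]
    return RepresentationMatrix(
        Z=np.concatenate(rows, axis=0), task_id=model.task_id, probe_hash=probe.hash
    )


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation of two equal-length vectors."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("pearson needs two equal-length vectors of size >= 2")
    ac = a - a.mean()
    bc = b - b.mean()
    va = float(ac @ ac) / a.size
    vb = float(bc @ bc) / b.size
    if va < VARIANCE_TOL or vb < VARIANCE_TOL:
        raise DegenerateRepresentationError("zero-variance vector in Pearson correlation")
    r = float(ac @ bc) / np.sqrt(float(ac @ ac) * float(bc @ bc))
    return float(np.clip(r, -1.0, 1.0))


def correlation_vector(Z: RepresentationMatrix) -> CorrelationVector:
    """Upper-triangle pairwise Pearson correlations of probe representations."""
    mat = Z.Z
    n = Z.n_probe
    if n < 2:
        raise ValueError("correlation vector needs at least 2 probe molecules")
    var = mat.var(axis=1)
    bad = np.flatnonzero(var < VARIANCE_TOL)
    if bad.size:
        raise DegenerateRepresentationError(
            f"constant representation for probe molecule index {int(bad[0])} "
            f"(task {Z.task_id!r})"
        )
    corr = np.corrcoef(mat)
    iu, ju = np.triu_indices(n, k=1)
    values = np.clip(corr[iu, ju], -1.0, 1.0)
    return CorrelationVector(values=values, task_id=Z.task_id, probe_hash=Z.probe_hash, n_probe=n)
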