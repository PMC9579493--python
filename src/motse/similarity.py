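"""Pairwise task similarity and similarity trees.

Two task embeddings are combined:

* local (attribution): s^A_{ij} = mean over probe molecules of the cosine
  between the two tasks' per-atom attribution vectors for that molecule;
* global (representation): s^R_{ij} = cosine between the two tasks'
  correlation vectors.

The combined similarity is the convex combination

    s_{ij} = (1 - lambda) * s^A_{ij} + lambda * s^R_{ij},

with weighting factor lambda = 0.7 by default. A similarity matrix over a
task collection is turned into a similarity tree by average-linkage
agglomerative clustering on the distance d = 1 - s, rendered as Newick.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .attribution import AttributionSet
from .mrsa import CorrelationVector

__all__ = [
    "TaskEmbedding",
    "TaskCollection",
    "SimilarityMatrix",
    "SimilarityTree",
    "AlignmentError",
    "DegenerateVectorError",
    "DEFAULT_LAMBDA",
    "cosine_sim",
    "attribution_similarity",
    "mrsa_similarity",
    "combined_similarity",
    "similarity_matrix",
    "similarity_tree",
]

DEFAULT_LAMBDA = 0.7


class AlignmentError(ValueError):
    """Raised when two embeddings do not share a probe set."""


class DegenerateVectorError(ValueError):
    """Raised on a zero vector where a direction is required."""


def cosine_sim(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.shape != b.shape:
        raise ValueError(f"cosine_sim shape mismatch {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-300 or nb < 1e-300:
        raise DegenerateVectorError("cosine similarity of a zero vector is undefined")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def attribution_similarity(Ai: AttributionSet, Aj: AttributionSet) -> float:
    """Local similarity: mean per-molecule cosine of attribution vectors."""
    if Ai.probe_hash != Aj.probe_hash:
        raise AlignmentError(
            f"attribution sets built on different probes "
            f"({Ai.probe_hash} vs {Aj.probe_hash})"
        )
    if len(Ai) != len(Aj):
        raise AlignmentError("attribution sets have different lengths")
    cosines = []
    for m, (vi, vj) in enumerate(zip(Ai.vectors, Aj.vectors)):
        if len(vi) != len(vj):
            raise AlignmentError(f"attribution length mismatch at probe molecule {m}")
        try:
            cosines.append(cosine_sim(vi.scores, vj.scores))
        except DegenerateVectorError as err:
            raise DegenerateVectorError(f"{err} (probe molecule {m})") from err
    return float(np.mean(cosines))


def mrsa_similarity(Ri: CorrelationVector, Rj: CorrelationVector) -> float:
    """Global similarity: cosine of the two correlation vectors."""
    if Ri.probe_hash != Rj.probe_hash:
        raise AlignmentError(
            f"correlation vectors built on different probes "
            f"({Ri.probe_hash} vs {Rj.probe_hash})"
        )
    if len(Ri) != len(Rj):
        raise AlignmentError("correlation vectors have different lengths")
    return cosine_sim(Ri.values, Rj.values)


def combined_similarity(sA: float, sR: float, lam: float = DEFAULT_LAMBDA) -> float:
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"weighting factor lambda must be in [0, 1], got {lam}")
    return (1.0 - lam) * sA + lam * sR


@dataclass
class TaskEmbedding:
    """The two latent-space placements of one task over a shared probe."""

    task_id: str
    attributions: AttributionSet
    correlations: CorrelationVector

    def __post_init__(self):
        if self.attributions.probe_hash != self.correlations.probe_hash:
            raise AlignmentError(
                f"task {self.task_id!r}: attribution and correlation embeddings "
                "use different probes"
            )

    @property
    def probe_hash(self) -> str:
        return self.attributions.probe_hash


@dataclass
class TaskCollection:
    """Tasks embedded over one shared probe set."""

    embeddings: List[TaskEmbedding]

    def __post_init__(self):
        if len(self.embeddings) < 2:
            raise ValueError("a task collection needs at least 2 tasks")
        hashes = {e.probe_hash for e in self.embeddings}
        if len(hashes) != 1:
            raise AlignmentError(f"tasks use {len(hashes)} different probe sets")

    @property
    def task_ids(self) -> List[str]:
        return [e.task_id for e in self.embeddings]

    def __len__(self) -> int:
        return len(self.embeddings)


@dataclass
class SimilarityMatrix:
    task_ids: List[str]
    S_attr: np.ndarray
    S_mrsa: np.ndarray
    S: np.ndarray
    lam: float

    def __post_init__(self):
        n = len(self.task_ids)
        for M in (self.S_attr, self.S_mrsa, self.S):
            if M.shape != (n, n):
                raise ValueError("similarity matrix shape mismatch")
            if not np.allclose(M, M.T, atol=1e-12):
                raise ValueError("similarity matrix must be symmetric")

    def value(self, ti: str, tj: str, which: str = "combined") -> float:
        M = {"combined": self.S, "attribution": self.S_attr, "mrsa": self.S_mrsa}[which]
        i, j = self.task_ids.index(ti), self.task_ids.index(tj)
        return float(M[i, j])

    def to_frame(self, which: str = "combined") -> pd.DataFrame:
        M = {"combined": self.S, "attribution": self.S_attr, "mrsa": self.S_mrsa}[which]
        return pd.DataFrame(M, index=self.task_ids, columns=self.task_ids)

    def write_csv(self, path, which: str = "combined") -> None:
        self.to_frame(which).to_csv(path, float_format="%.10f")

    def to_json(self) -> str:
        return json.dumps(
            {
                "task_ids": self.task_ids,
                "lambda": self.lam,
                "S_attr": self.S_attr.tolist(),
                "S_mrsa": self.S_mrsa.tolist(),
                "S": self.S.tolist(),
            }
        )


def similarity_matrix(tc: TaskCollection, lam: float = DEFAULT_LAMBDA) -> SimilarityMatrix:
    """All-pairs local, global, and combined similarity; diagonal fixed at 1."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"weighting factor lambda must be in [0, 1], got {lam}")
    n = len(tc)
    S_attr = np.eye(n)
    S_mrsa = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sA = attribution_similarity(tc.embeddings[i].attributions, tc.embeddings[j].attributions)
            sR = mrsa_similarity(tc.embeddings[i].correlations, tc.embeddings[j].correlations)
            S_attr[i, j] = S_attr[j, i] = sA
            S_mrsa[i, j] = S_mrsa[j, i] = sR
    S = (1.0 - lam) * S_attr + lam * S_mrsa
    np.fill_diagonal(S, 1.0)
    return SimilarityMatrix(task_ids=list(tc.task_ids), S_attr=S_attr, S_mrsa=S_mrsa, S=S, lam=lam)


@dataclass
class SimilarityTree:
    """Agglomerative merge tree over tasks, with Newick rendering."""

    leaf_labels: List[str]
    linkage: np.ndarray  # scipy linkage matrix
    newick: str


def _newick_label(label: str) -> str:
    # quote anything outside the safe unquoted charset (unquoted "_" would
    # be read back as a space by Newick parsers)
    if label and all(c.isalnum() or c in ".-" for c in label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = sch.to_tree(link)

    def render(node, parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{_newick_label(labels[node.id])}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    return render(tree, tree.dist) + ";"


def similarity_tree(S: SimilarityMatrix, which: str = "combined") -> SimilarityTree:
    """Average-linkage clustering on distance d = 1 - s, as a rooted tree.

    Branch lengths are differences of merge heights, so the root-to-leaf
    depth of any leaf equals the final merge height.
    """
    M = {"combined": S.S, "attribution": S.S_attr, "mrsa": S.S_mrsa}[which]
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    condensed = ssd.squareform(D, checks=False)
    link = sch.linkage(condensed, method="average")
    newick = _linkage_to_newick(link, S.task_ids)
    return SimilarityTree(leaf_labels=list(S.task_ids), linkage=link, newick=newick)
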