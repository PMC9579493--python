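"""Task datasets, probe sets, and the transfer-evaluation splits.

A :class:`TaskDataset` holds labeled molecules for one prediction task and a
train/valid/test split. :func:`make_transfer_split` reproduces the data-poor
transfer scenario: a "large" source-scale split (8:1:1) and a "small"
target-scale subset (800 train / 100 valid) that shares the large split's
test set so both scales are evaluated on identical held-out molecules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .molecules import (
    MolecularGraph,
    ParseError,
    graph_from_dict,
    graph_to_dict,
    molecules_hash,
    parse_smiles,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TaskDataset",
    "ProbeSet",
    "DatasetError",
    "load_task_dataset",
    "random_split",
    "make_transfer_split",
    "sample_probe",
]

SPLIT_NAMES = ("train", "valid", "test")
DEFAULT_PROBE_SIZE = 500


class DatasetError(ValueError):
    """Raised for empty, malformed, or undersized datasets."""


@dataclass
class TaskDataset:
    """Labeled molecules for one task, with split assignment.

    ``splits[k]`` is the split of record k ("train"/"valid"/"test").
    ``label_stats`` (train-set mean, sd) is used to z-score regression
    labels during training and de-standardize predictions.
    """

    task_id: str
    task_type: str  # "regression" | "classification"
    molecules: List[MolecularGraph]
    labels: np.ndarray
    splits: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.task_type not in ("regression", "classification"):
            raise DatasetError(f"unknown task type {self.task_type!r}")
        self.labels = np.asarray(self.labels, dtype=np.float64)
        if len(self.molecules) != len(self.labels):
            raise DatasetError("molecules and labels length mismatch")
        if len(self.molecules) == 0:
            raise DatasetError(f"dataset for task {self.task_id!r} is empty")
        if self.task_type == "classification" and not np.isin(self.labels, (0.0, 1.0)).all():
            bad = self.labels[~np.isin(self.labels, (0.0, 1.0))][0]
            raise DatasetError(f"classification label {bad!r} outside {{0,1}}")
        if self.splits is None:
            self.splits = np.array(["train"] * len(self.labels), dtype=object)
        self.splits = np.asarray(self.splits, dtype=object)
        if len(self.splits) != len(self.labels):
            raise DatasetError("splits length mismatch")
        if not np.isin(self.splits, SPLIT_NAMES).all():
            raise DatasetError("split values must be train/valid/test")

    def __len__(self) -> int:
        return len(self.labels)

    def indices(self, split: str) -> np.ndarray:
        return np.flatnonzero(self.splits == split)

    def subset(self, idx: np.ndarray, splits: Optional[np.ndarray] = None) -> "TaskDataset":
        idx = np.asarray(idx, dtype=np.intp)
        return TaskDataset(
            task_id=self.task_id,
            task_type=self.task_type,
            molecules=[self.molecules[i] for i in idx],
            labels=self.labels[idx],
            splits=self.splits[idx] if splits is None else np.asarray(splits, dtype=object),
        )

    @property
    def label_stats(self) -> Tuple[float, float]:
        """(mean, sd) of train labels; sd floored at a tiny positive value."""
        train = self.labels[self.splits == "train"]
        if train.size == 0:
            raise DatasetError(f"task {self.task_id!r} has no train split")
        sd = float(train.std())
        return float(train.mean()), max(sd, 1e-12)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles_or_id": [g.source_id for g in self.molecules],
                "task_name": self.task_id,
                "label": self.labels,
                "split": self.splits,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_molecules_json(self, path) -> None:
        Path(path).write_text(
            json.dumps([graph_to_dict(g) for g in self.molecules], sort_keys=True)
        )


@dataclass
class ProbeSet:
    """Fixed, ordered set of unlabeled molecules shared by every task.

    Every task model is run over the same probe in the same order, so the
    per-molecule attribution vectors and representation rows of different
    tasks are position-aligned. ``hash`` identifies (content + order) and is
    checked before any cross-task comparison.
    """

    molecules: List[MolecularGraph]
    seed: int = 0
    source: str = ""

    def __post_init__(self):
        if len(self.molecules) < 2:
            raise DatasetError("probe set needs at least 2 molecules")
        ids = [g.source_id for g in self.molecules]
        if len(set(ids)) != len(ids):
            raise DatasetError("probe set contains duplicate source_ids")

    def __len__(self) -> int:
        return len(self.molecules)

    @property
    def hash(self) -> str:
        return molecules_hash(self.molecules)

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "source": self.source,
                "hash": self.hash,
                "molecules": [graph_to_dict(g) for g in self.molecules],
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ProbeSet":
        d = json.loads(text)
        return cls(
            molecules=[graph_from_dict(m) for m in d["molecules"]],
            seed=int(d.get("seed", 0)),
            source=str(d.get("source", "")),
        )


def load_task_dataset(
    path,
    smiles_col: str = "smiles",
    label_col: str = "label",
    task_type: str = "regression",
    task_id: Optional[str] = None,
    delimiter: str = ",",
) -> TaskDataset:
    """Load a delimited text table of (SMILES, label[, split]) rows.

    Rows whose SMILES cannot be parsed are dropped with a logged count; an
    all-unparsable table is an error.
    """
    df = pd.read_csv(path, sep=delimiter)
    for col in (smiles_col, label_col):
        if col not in df.columns:
            raise DatasetError(f"column {col!r} missing from {path}")
    molecules, labels, splits = [], [], []
    n_dropped = 0
    has_split = "split" in df.columns
    for _, row in df.iterrows():
        try:
            g = parse_smiles(str(row[smiles_col]))
        except ParseError:
            n_dropped += 1
            continue
        molecules.append(g)
        labels.append(float(row[label_col]))
        splits.append(str(row["split"]) if has_split else "train")
    if n_dropped:
        logger.warning("dropped %d unparsable rows from %s", n_dropped, path)
    if not molecules:
        raise DatasetError(f"no parsable molecules in {path}")
    return TaskDataset(
        task_id=task_id if task_id is not None else label_col,
        task_type=task_type,
        molecules=molecules,
        labels=np.asarray(labels),
        splits=np.asarray(splits, dtype=object),
    )


def random_split(
    n: int, seed: int, fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
) -> np.ndarray:
    """Seeded 8:1:1-style split assignment for ``n`` records."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(fractions[0] * n)
    n_valid = int(fractions[1] * n)
    splits = np.empty(n, dtype=object)
    splits[order[:n_train]] = "train"
    splits[order[n_train : n_train + n_valid]] = "valid"
    splits[order[n_train + n_valid :]] = "test"
    return splits


def make_transfer_split(
    d: TaskDataset,
    seed: int,
    n_small_train: int = 800,
    n_small_valid: int = 100,
) -> Tuple[TaskDataset, TaskDataset]:
    """Build the (large, small) dataset pair for a transfer experiment.

    large: ``d`` partitioned train/valid/test 8:1:1 by seeded shuffle.
    small: ``n_small_train`` records sampled from large.train and
    ``n_small_valid`` from large.valid; the test records are the *same
    objects* as large's test set, so both scales share one evaluation set
    and no small-split record can leak into it.
    """
    if len(d) < 1000:
        raise DatasetError(f"transfer split needs >= 1000 records, got {len(d)}")
    rng = np.random.default_rng(seed)
    splits = random_split(len(d), seed)
    large = d.subset(np.arange(len(d)), splits=splits)
    train_idx = large.indices("train")
    valid_idx = large.indices("valid")
    test_idx = large.indices("test")
    if len(train_idx) < n_small_train or len(valid_idx) < n_small_valid:
        raise DatasetError("large split too small for the requested small subset")
    small_train = rng.choice(train_idx, size=n_small_train, replace=False)
    small_valid = rng.choice(valid_idx, size=n_small_valid, replace=False)
    idx = np.concatenate([small_train, small_valid, test_idx])
    small_splits = np.array(
        ["train"] * n_small_train + ["valid"] * n_small_valid + ["test"] * len(test_idx),
        dtype=object,
    )
    small = TaskDataset(
        task_id=large.task_id,
        task_type=large.task_type,
        molecules=[d.molecules[i] for i in idx],
        labels=d.labels[idx],
        splits=small_splits,
    )
    return large, small


def sample_probe(
    pool: Sequence[MolecularGraph],
    n: int = DEFAULT_PROBE_SIZE,
    seed: int = 0,
    source: str = "",
) -> ProbeSet:
    """Uniform sample of ``n`` probe molecules without replacement."""
    if len(pool) < n:
        raise DatasetError(f"probe pool has {len(pool)} < {n} molecules")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return ProbeSet(molecules=[pool[i] for i in idx], seed=seed, source=source)
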