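"""End-to-end experiment pipeline with a single config and fixed seeds.

Stages: simulate (or load) task datasets -> build the large/small transfer
splits -> train small-scale models for similarity estimation -> extract
attribution and representation-correlation embeddings over a shared probe
-> similarity matrix + tree -> pre-train large-scale source models ->
similarity-guided transfer experiment on the target task.

Task similarity is estimated from the models trained on the *small*
(target-scale) datasets, while transfer pre-training uses the *large*
datasets; the two model registries are kept distinct throughout.

Every artifact is written with provenance: the config hash, the global
seed and the probe hash that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import yaml

from .datasets import ProbeSet, TaskDataset, load_task_dataset, make_transfer_split, sample_probe
from .attribution import attribution_set
from .model import TaskModel, TrainConfig, save_model, train_task_model
from .mrsa import correlation_vector, embed_probe
from .similarity import (
    DEFAULT_LAMBDA,
    SimilarityMatrix,
    TaskCollection,
    TaskEmbedding,
    similarity_matrix,
    similarity_tree,
)
from .synthetic import GeneratorConfig, build_benchmark, generate_molecules
from .transfer import DEFAULT_N_SOURCES, rank_sources, run_transfer_experiment

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "embed_task", "config_hash"]


class PipelineError(RuntimeError):
    """Raised with the failing stage name when a pipeline stage aborts."""


@dataclass
class RunConfig:
    """Validated configuration for one full experiment."""

    out_dir: str
    seed: int = 0
    n_molecules: int = 1000
    n_probe: int = 200
    lam: float = DEFAULT_LAMBDA
    n_sources: int = DEFAULT_N_SOURCES
    target_task: str = "NHOHCount"
    run_transfer: bool = True
    train: TrainConfig = field(default_factory=lambda: TrainConfig(hidden_dim=64))
    # optional external datasets: task_id -> CSV path (else synthetic benchmark)
    datasets: Optional[Dict[str, str]] = None
    smiles_col: str = "smiles"
    label_col: str = "label"
    task_type: str = "regression"

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")
        if self.n_probe < 2:
            raise ValueError("n_probe must be >= 2")
        if self.datasets is not None:
            missing = [p for p in self.datasets.values() if not Path(p).exists()]
            if missing:
                raise FileNotFoundError(f"dataset paths do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        train = TrainConfig(**raw.pop("train", {}))
        return cls(train=train, **raw)


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _task_seed(base: int, task_id: str) -> int:
    h = hashlib.sha256(f"{base}:{task_id}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def embed_task(model: TaskModel, probe: ProbeSet) -> TaskEmbedding:
    """Both latent-space placements of one trained task model."""
    attrs = attribution_set(model, probe)
    corr = correlation_vector(embed_probe(model, probe))
    return TaskEmbedding(task_id=model.task_id, attributions=attrs, correlations=corr)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the experiment directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    provenance = {"config_hash": chash, "seed": cfg.seed}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    # -- datasets ----------------------------------------------------------
    name = stage("simulate/load")
    try:
        if cfg.datasets is None:
            gen = GeneratorConfig(seed=cfg.seed)
            tasks = build_benchmark(gen, cfg.n_molecules)
        else:
            tasks = {
                tid: load_task_dataset(
                    path, cfg.smiles_col, cfg.label_col, cfg.task_type, task_id=tid
                )
                for tid, path in cfg.datasets.items()
            }
        (out / "datasets").mkdir(exist_ok=True)
        for tid, d in tasks.items():
            d.write_csv(out / "datasets" / f"{tid}.csv")
        next(iter(tasks.values())).write_molecules_json(out / "datasets" / "molecules.json")
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    # -- probe (independent pool, disjoint from every task's molecules) ----
    name = stage("probe")
    try:
        probe_pool = generate_molecules(
            GeneratorConfig(seed=_task_seed(cfg.seed, "probe-pool")), 2 * cfg.n_probe
        )
        probe = sample_probe(probe_pool, cfg.n_probe, seed=cfg.seed, source="synthetic-pool")
        (out / "probe.json").write_text(probe.to_json())
        provenance["probe_hash"] = probe.hash
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    # -- transfer splits ---------------------------------------------------
    name = stage("split")
    try:
        large: Dict[str, TaskDataset] = {}
        small: Dict[str, TaskDataset] = {}
        for tid, d in tasks.items():
            large[tid], small[tid] = make_transfer_split(d, seed=cfg.seed)
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    # -- similarity models (small scale) + embeddings ----------------------
    name = stage("train-similarity-models")
    try:
        (out / "models_small").mkdir(exist_ok=True)
        embeddings: List[TaskEmbedding] = []
        for tid in sorted(tasks):
            tcfg = dataclasses.replace(cfg.train, seed=_task_seed(cfg.seed, f"small:{tid}"))
            model = train_task_model(small[tid], tcfg)
            save_model(model, out / "models_small" / f"{tid}.npz")
            embeddings.append(embed_task(model, probe))
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    # -- similarity matrix + tree ------------------------------------------
    name = stage("similarity")
    try:
        S = similarity_matrix(TaskCollection(embeddings), lam=cfg.lam)
        S.write_csv(out / "similarity.csv")
        S.write_csv(out / "similarity_attr.csv", which="attribution")
        S.write_csv(out / "similarity_mrsa.csv", which="mrsa")
        (out / "similarity.json").write_text(S.to_json())
        tree = similarity_tree(S)
        (out / "similarity_tree.nwk").write_text(tree.newick + "\n")
    except Exception as err:
        raise PipelineError(f"stage {name!r} failed: {err}") from err

    # -- transfer experiment ------------------------------------------------
    if cfg.run_transfer:
        name = stage("transfer")
        try:
            if cfg.target_task not in tasks:
                raise KeyError(f"target task {cfg.target_task!r} not among tasks")
            plan = rank_sources(S, cfg.target_task, n=min(cfg.n_sources, len(tasks) - 1))
            (out / "models_large").mkdir(exist_ok=True)
            sources: Dict[str, TaskModel] = {}
            for tid, _sim in plan.ranked_sources:
                tcfg = dataclasses.replace(cfg.train, seed=_task_seed(cfg.seed, f"large:{tid}"))
                sources[tid] = train_task_model(large[tid], tcfg)
                save_model(sources[tid], out / "models_large" / f"{tid}.npz")
            tcfg = dataclasses.replace(cfg.train, seed=_task_seed(cfg.seed, f"target:{cfg.target_task}"))
            result = run_transfer_experiment(plan, sources, small[cfg.target_task], tcfg)
            (out / "transfer.json").write_text(
                json.dumps(
                    {
                        "plan": {
                            "target": plan.target_task_id,
                            "ranked_sources": plan.ranked_sources,
                            "low_similarity": plan.low_similarity,
                        },
                        "result": asdict(result),
                        **provenance,
                    },
                    indent=2,
                )
            )
        except Exception as err:
            raise PipelineError(f"stage {name!r} failed: {err}") from err

    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return out
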