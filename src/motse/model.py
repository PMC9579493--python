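"""Per-task graph convolutional models: architecture, training, persistence.

Each prediction task gets its own model ``m = p(e(.))``: a GCN encoder
``e`` (three graph-convolution layers with symmetric degree normalization
and self-loops, followed by a dual readout concatenating a learned-gate
weighted-sum pool and an elementwise max pool) and a two-layer fully
connected predictor ``p`` ending in a single scalar (regression value on
the z-scored label scale, or classification logit).

Layer rule (node v, layer l):

    h_v^{l+1} = ReLU( W^l  sum_{u in N(v) ∪ {v}}  h_u^l / sqrt((d_v+1)(d_u+1)) )

Training uses Adam (learning rate 1e-4, weight decay 1e-5 by default) for
at most 200 epochs with early stopping once the validation loss has not
improved for 20 consecutive epochs; the weights achieving the best
validation loss are returned.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.sparse as sp

from . import autodiff as ad
from .autodiff import Tensor
from .datasets import TaskDataset
from .molecules import FEATURE_SCHEMA_ID, MolecularGraph, N_FEATURES, featurize

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TaskModel",
    "DivergenceError",
    "FormatError",
    "train_task_model",
    "encode",
    "predict",
    "save_model",
    "load_model",
]

MODEL_FORMAT = "motse-model-v1"


class DivergenceError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class FormatError(ValueError):
    """Raised on a model file with an unknown format or feature schema."""


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters shared by pre-training and fine-tuning."""

    hidden_dim: int = 256
    n_gcn_layers: int = 3
    predictor_hidden: int = 256
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    max_epochs: int = 200
    patience: int = 20
    dropout: float = 0.0
    seed: int = 0
    batch_size: int = 64

    def __post_init__(self):
        if min(self.hidden_dim, self.n_gcn_layers, self.predictor_hidden, self.batch_size) < 1:
            raise ValueError("model dimensions and batch size must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be positive, weight_decay nonnegative")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.dropout != 0.0:
            raise ValueError("dropout is fixed at 0 in this architecture")


# ---------------------------------------------------------------------------
# Graph batching
# ---------------------------------------------------------------------------

@dataclass
class _PreppedGraph:
    """Featurized molecule with its normalized self-loop adjacency (COO)."""

    X: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray


def prepare_graph(g: MolecularGraph) -> _PreppedGraph:
    if g.n_atoms == 0:
        raise ValueError(f"empty graph {g.source_id!r}")
    X = featurize(g)
    n = g.n_atoms
    deg = g.degrees().astype(np.float64)
    inv_sqrt = 1.0 / np.sqrt(deg + 1.0)
    rows = [np.arange(n)]
    cols = [np.arange(n)]
    vals = [inv_sqrt * inv_sqrt]
    for i, j, _order in g.bonds:
        rows.append(np.array([i, j]))
        cols.append(np.array([j, i]))
        v = inv_sqrt[i] * inv_sqrt[j]
        vals.append(np.array([v, v]))
    return _PreppedGraph(
        X=X,
        rows=np.concatenate(rows).astype(np.intp),
        cols=np.concatenate(cols).astype(np.intp),
        vals=np.concatenate(vals),
    )


def build_batch(prepped: Sequence[_PreppedGraph]) -> Tuple[np.ndarray, sp.csr_matrix, np.ndarray]:
    """Stack molecules into one feature matrix + block-diagonal adjacency."""
    sizes = np.array([p.X.shape[0] for p in prepped], dtype=np.intp)
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    n_total = int(sizes.sum())
    X = np.concatenate([p.X for p in prepped], axis=0)
    rows = np.concatenate([p.rows + o for p, o in zip(prepped, offsets)])
    cols = np.concatenate([p.cols + o for p, o in zip(prepped, offsets)])
    vals = np.concatenate([p.vals for p in prepped])
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_total, n_total))
    return X, A, offsets


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(cfg: TrainConfig, n_features: int = N_FEATURES) -> Dict[str, Tensor]:
    rng = np.random.default_rng(cfg.seed)
    h = cfg.hidden_dim
    params: Dict[str, Tensor] = {}
    in_dim = n_features
    for l in range(cfg.n_gcn_layers):
        params[f"gcn{l}.W"] = Tensor(_glorot(rng, in_dim, h), requires_grad=True)
        in_dim = h
    params["gate.W"] = Tensor(_glorot(rng, h, 1), requires_grad=True)
    params["gate.b"] = Tensor(np.zeros(1), requires_grad=True)
    d_enc = 2 * h
    params["fc1.W"] = Tensor(_glorot(rng, d_enc, cfg.predictor_hidden), requires_grad=True)
    params["fc1.b"] = Tensor(np.zeros(cfg.predictor_hidden), requires_grad=True)
    params["fc2.W"] = Tensor(_glorot(rng, cfg.predictor_hidden, 1), requires_grad=True)
    params["fc2.b"] = Tensor(np.zeros(1), requires_grad=True)
    return params


class TaskModel:
    """A trained (or initialized) encoder + predictor for one task."""

    def __init__(
        self,
        config: TrainConfig,
        task_id: str,
        task_type: str,
        label_stats: Tuple[float, float] = (0.0, 1.0),
        params: Optional[Dict[str, Tensor]] = None,
        schema_id: str = FEATURE_SCHEMA_ID,
        training_log: Optional[List[dict]] = None,
    ):
        self.config = config
        self.task_id = task_id
        self.task_type = task_type
        self.label_stats = (float(label_stats[0]), float(label_stats[1]))
        self.schema_id = schema_id
        self.params = params if params is not None else init_params(config)
        self.training_log = training_log if training_log is not None else []

    @property
    def d_enc(self) -> int:
        return 2 * self.config.hidden_dim

    def copy(self) -> "TaskModel":
        return TaskModel(
            config=self.config,
            task_id=self.task_id,
            task_type=self.task_type,
            label_stats=self.label_stats,
            params={k: Tensor(v.value.copy(), requires_grad=True) for k, v in self.params.items()},
            schema_id=self.schema_id,
            training_log=[dict(e) for e in self.training_log],
        )

    # -- forward passes ----------------------------------------------------

    def encode_tensor(self, X: Tensor, A: sp.csr_matrix, offsets: np.ndarray) -> Tensor:
        h = X
        for l in range(self.config.n_gcn_layers):
            h = ad.relu(ad.matmul(ad.spmm(A, h), self.params[f"gcn{l}.W"]))
        gate = ad.sigmoid(ad.add(ad.matmul(h, self.params["gate.W"]), self.params["gate.b"]))
        weighted = ad.segment_sum(ad.mul(gate, h), offsets)
        pooled_max = ad.segment_max(h, offsets)
        return ad.concat([weighted, pooled_max], axis=1)

    def output_tensor(self, X: Tensor, A: sp.csr_matrix, offsets: np.ndarray) -> Tensor:
        rep = self.encode_tensor(X, A, offsets)
        hid = ad.relu(ad.add(ad.matmul(rep, self.params["fc1.W"]), self.params["fc1.b"]))
        return ad.add(ad.matmul(hid, self.params["fc2.W"]), self.params["fc2.b"])

    def _run(self, graphs: Sequence[MolecularGraph], what: str) -> np.ndarray:
        prepped = [prepare_graph(g) for g in graphs]
        X, A, offsets = build_batch(prepped)
        xt = Tensor(X)
        if what == "encode":
            return self.encode_tensor(xt, A, offsets).value
        return self.output_tensor(xt, A, offsets).value[:, 0]

    def encode(self, graphs: Union[MolecularGraph, Sequence[MolecularGraph]]) -> np.ndarray:
        """Molecule-level representation(s), dimension 2 x hidden."""
        if isinstance(graphs, MolecularGraph):
            return self._run([graphs], "encode")[0]
        return self._run(list(graphs), "encode")

    def raw_output(self, graphs: Union[MolecularGraph, Sequence[MolecularGraph]]) -> np.ndarray:
        """Model output on the training scale: z-scored value or logit."""
        if isinstance(graphs, MolecularGraph):
            return self._run([graphs], "output")[0]
        return self._run(list(graphs), "output")

    def predict(self, graphs: Union[MolecularGraph, Sequence[MolecularGraph]]) -> np.ndarray:
        """De-standardized prediction (regression) or logit (classification)."""
        out = self.raw_output(graphs)
        if self.task_type == "regression":
            mean, sd = self.label_stats
            return out * sd + mean
        return out

    def predict_proba(self, graphs) -> np.ndarray:
        if self.task_type != "classification":
            raise ValueError("predict_proba is only defined for classification tasks")
        return 1.0 / (1.0 + np.exp(-self.raw_output(graphs)))


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    """Adam with L2 weight decay added to the gradient (framework convention)."""

    def __init__(self, params: Dict[str, Tensor], lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v.value) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.value) for k, v in params.items()}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            if self.wd:
                g = g + self.wd * p.value
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _batch_loss(model: TaskModel, prepped, targets: np.ndarray) -> Tensor:
    X, A, offsets = build_batch(prepped)
    out = model.output_tensor(Tensor(X), A, offsets)
    if model.task_type == "regression":
        return ad.mean_square(out, targets.reshape(-1, 1))
    return ad.bce_with_logits(out, targets.reshape(-1, 1))


def train_task_model(
    d: TaskDataset,
    cfg: TrainConfig,
    init_model: Optional[TaskModel] = None,
) -> TaskModel:
    """Train a task model with Adam + early stopping on validation loss.

    ``init_model`` seeds the weights (fine-tuning); otherwise weights are
    freshly initialized from ``cfg.seed``. Regression labels are z-scored
    with the train-split statistics of ``d``.
    """
    train_idx = d.indices("train")
    valid_idx = d.indices("valid")
    if len(train_idx) == 0 or len(valid_idx) == 0:
        raise ValueError(f"task {d.task_id!r} needs nonempty train and valid splits")
    mean, sd = d.label_stats if d.task_type == "regression" else (0.0, 1.0)
    labels = (d.labels - mean) / sd if d.task_type == "regression" else d.labels

    if init_model is not None:
        model = init_model.copy()
        model.task_id = d.task_id
        model.task_type = d.task_type
        model.training_log = []
    else:
        model = TaskModel(config=cfg, task_id=d.task_id, task_type=d.task_type)
    model.config = cfg
    model.label_stats = (mean, sd)

    if cfg.max_epochs == 0:
        return model

    prepped = {int(i): prepare_graph(d.molecules[i]) for i in np.concatenate([train_idx, valid_idx])}
    valid_batches = [
        ([prepped[int(i)] for i in valid_idx[k : k + cfg.batch_size]],
         labels[valid_idx[k : k + cfg.batch_size]])
        for k in range(0, len(valid_idx), cfg.batch_size)
    ]
    opt = _Adam(model.params, cfg.learning_rate, cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    best_loss = np.inf
    best_params: Dict[str, np.ndarray] = {}
    best_epoch = -1
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for k in range(0, len(order), cfg.batch_size):
            idx = order[k : k + cfg.batch_size]
            loss = _batch_loss(model, [prepped[int(i)] for i in idx], labels[idx])
            if not np.isfinite(loss.value):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.value) * len(idx))
        valid_losses = [float(_batch_loss(model, pb, tb).value) * len(tb) for pb, tb in valid_batches]
        train_loss = sum(train_losses) / len(train_idx)
        valid_loss = sum(valid_losses) / len(valid_idx)
        if not np.isfinite(valid_loss):
            raise DivergenceError(f"non-finite validation loss at epoch {epoch}")
        model.training_log.append(
            {"epoch": epoch, "train_loss": train_loss, "valid_loss": valid_loss}
        )
        if valid_loss < best_loss:
            best_loss = valid_loss
            best_epoch = epoch
            best_params = {k: v.value.copy() for k, v in model.params.items()}
        elif epoch - best_epoch >= cfg.patience:
            break
    for k, v in best_params.items():
        model.params[k].value = v
    logger.info(
        "task %s: stopped after %d epochs, best valid loss %.5f (epoch %d)",
        d.task_id, len(model.training_log), best_loss, best_epoch,
    )
    return model


# Thin functional wrappers over the model surface.

def encode(model: TaskModel, g: MolecularGraph) -> np.ndarray:
    return model.encode(g)


def predict(model: TaskModel, g: MolecularGraph) -> float:
    return float(model.predict(g))


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TaskModel, path) -> None:
    """Self-describing single-file archive: weights + embedded JSON config."""
    meta = {
        "format": MODEL_FORMAT,
        "schema_id": model.schema_id,
        "task_id": model.task_id,
        "task_type": model.task_type,
        "label_stats": list(model.label_stats),
        "config": asdict(model.config),
        "training_log": model.training_log,
    }
    arrays = {f"param::{k}": v.value for k, v in model.params.items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TaskModel:
    with np.load(path) as archive:
        if "meta" not in archive:
            raise FormatError(f"{path} is not a task-model archive")
        meta = json.loads(bytes(archive["meta"]).decode())
        if meta.get("format") != MODEL_FORMAT:
            raise FormatError(f"unknown model format {meta.get('format')!r}")
        if meta.get("schema_id") != FEATURE_SCHEMA_ID:
            raise FormatError(f"unknown feature schema {meta.get('schema_id')!r}")
        params = {
            k[len("param::"):]: Tensor(archive[k].copy(), requires_grad=True)
            for k in archive.files
            if k.startswith("param::")
        }
    return TaskModel(
        config=TrainConfig(**meta["config"]),
        task_id=meta["task_id"],
        task_type=meta["task_type"],
        label_stats=tuple(meta["label_stats"]),
        params=params,
        schema_id=meta["schema_id"],
        training_log=meta["training_log"],
    )
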