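"""Encoder/predictor contracts, training behavior, and persistence."""

import numpy as np
import pytest

from motse.model import (
    FormatError,
    TaskModel,
    TrainConfig,
    load_model,
    save_model,
    train_task_model,
)
from motse.molecules import MolecularGraph, parse_smiles
from motse.synthetic import GeneratorConfig, build_benchmark, generate_molecules
from tests.conftest import TINY_CFG


def test_encoder_output_dimension_is_twice_hidden():
    model = TaskModel(TrainConfig(hidden_dim=256), "t", "regression")
    rep = model.encode(parse_smiles("CCO"))
    assert rep.shape == (512,)
    small = TaskModel(TrainConfig(hidden_dim=8, predictor_hidden=16), "t", "regression")
    assert small.encode(parse_smiles("CCO")).shape == (16,)


def test_single_atom_graph_readout_is_gate_times_h_concat_h():
    model = TaskModel(TrainConfig(hidden_dim=8, predictor_hidden=16, seed=3), "t", "regression")
    g = parse_smiles("C")
    from motse import autodiff as ad
    from motse.autodiff import Tensor
    from motse.model import build_batch, prepare_graph

    X, A, off = build_batch([prepare_graph(g)])
    h = Tensor(X)
    for l in range(model.config.n_gcn_layers):
        h = ad.relu(ad.matmul(ad.spmm(A, h), model.params[f"gcn{l}.W"]))
    gate = 1 / (1 + np.exp(-(h.value @ model.params["gate.W"].value + model.params["gate.b"].value)))
    expected = np.concatenate([gate[0] * h.value[0], h.value[0]])
    assert np.allclose(model.encode(g), expected)


def test_encoder_is_permutation_invariant():
    rng = np.random.default_rng(0)
    model = TaskModel(TrainConfig(hidden_dim=8, predictor_hidden=16, seed=1), "t", "regression")
    for g in generate_molecules(GeneratorConfig(seed=6), 10):
        perm = rng.permutation(g.n_atoms)
        inv = np.argsort(perm)
        g2 = MolecularGraph(
            atoms=[g.atoms[i] for i in perm],
            bonds=[(int(inv[i]), int(inv[j]), o) for i, j, o in g.bonds],
            source_id="perm",
        )
        assert np.allclose(model.encode(g), model.encode(g2), atol=1e-12)


def test_fresh_model_prediction_is_reproducible():
    g = parse_smiles("CCO")
    a = TaskModel(TrainConfig(hidden_dim=8, seed=5), "t", "regression").predict(g)
    b = TaskModel(TrainConfig(hidden_dim=8, seed=5), "t", "regression").predict(g)
    assert float(a) == float(b)


def test_regression_destandardization_inverts_zscore():
    model = TaskModel(TrainConfig(hidden_dim=8), "t", "regression", label_stats=(7.0, 2.0))
    g = parse_smiles("CCO")
    raw = model.raw_output(g)
    assert float(model.predict(g)) == pytest.approx(float(raw) * 2.0 + 7.0)


def test_classification_probability_in_unit_interval(bench300):
    d = bench300["NHD"]
    labels = (d.labels > 0).astype(float)
    from motse.datasets import TaskDataset

    cd = TaskDataset("hasNHD", "classification", d.molecules, labels, d.splits.copy())
    model = train_task_model(cd, TINY_CFG)
    p = model.predict_proba(d.molecules[:20])
    assert ((p > 0) & (p < 1)).all()


def test_training_is_deterministic(bench300):
    m1 = train_task_model(bench300["NOCount"], TINY_CFG)
    m2 = train_task_model(bench300["NOCount"], TINY_CFG)
    assert m1.training_log == m2.training_log
    for k in m1.params:
        assert np.array_equal(m1.params[k].value, m2.params[k].value)


def test_early_stopping_returns_best_validation_weights(tiny_model, bench300):
    log = tiny_model.training_log
    assert 0 < len(log) <= TINY_CFG.max_epochs
    best = min(e["valid_loss"] for e in log)
    # re-evaluating the returned weights reproduces the best logged loss
    d = bench300["NOCount"]
    idx = d.indices("valid")
    mean, sd = d.label_stats
    pred = tiny_model.raw_output([d.molecules[i] for i in idx])
    mse = float(np.mean((pred - (d.labels[idx] - mean) / sd) ** 2))
    assert mse == pytest.approx(best, rel=1e-9)


def test_trained_model_beats_the_mean_baseline():
    tasks = build_benchmark(GeneratorConfig(seed=21), 500)
    d = tasks["NOCount"]
    cfg = TrainConfig(hidden_dim=64, max_epochs=60, seed=0)
    model = train_task_model(d, cfg)
    best_valid = min(e["valid_loss"] for e in model.training_log)
    # z-scored MSE of 1.0 is the predict-the-train-mean baseline
    assert best_valid < 1.0


def test_epoch_count_never_exceeds_max(tiny_model):
    assert len(tiny_model.training_log) <= TINY_CFG.max_epochs


def test_zero_epoch_training_returns_initialized_model(bench300):
    cfg = TrainConfig(hidden_dim=8, predictor_hidden=16, max_epochs=0, seed=0)
    model = train_task_model(bench300["NOCount"], cfg)
    assert model.training_log == []
    fresh = TaskModel(cfg, "NOCount", "regression")
    for k in model.params:
        assert np.array_equal(model.params[k].value, fresh.params[k].value)


def test_save_load_round_trip_is_bit_exact(tmp_path, tiny_model, bench300):
    g = bench300["NOCount"].molecules[0]
    before = tiny_model.predict(g)
    path = tmp_path / "model.npz"
    save_model(tiny_model, path)
    loaded = load_model(path)
    assert float(loaded.predict(g)) == float(before)
    assert loaded.task_id == tiny_model.task_id
    assert loaded.config == tiny_model.config
    assert loaded.training_log == tiny_model.training_log


def test_load_rejects_foreign_archives(tmp_path):
    bad = tmp_path / "bad.npz"
    np.savez(bad, a=np.zeros(3))
    with pytest.raises(FormatError):
        load_model(bad)


def test_empty_graph_is_an_input_error():
    from motse.model import prepare_graph

    with pytest.raises(ValueError):
        prepare_graph(MolecularGraph(atoms=[], bonds=[], source_id="empty"))


def test_gradients_exist_and_are_finite_on_fixture_graphs(tiny_model, probe20):
    from motse import autodiff as ad
    from motse.autodiff import Tensor
    from motse.model import build_batch, prepare_graph

    for g in probe20.molecules[:5]:
        X, A, off = build_batch([prepare_graph(g)])
        xt = Tensor(X, requires_grad=True)
        ad.total_sum(tiny_model.output_tensor(xt, A, off)).backward()
        assert xt.grad is not None and np.isfinite(xt.grad).all()
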