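"""Gradient*Input attribution: closed-form oracles and alignment rules."""

import numpy as np
import pytest

from motse import autodiff as ad
from motse.autodiff import Tensor
from motse.attribution import (
    AttributionError,
    AttributionVector,
    attribution_set,
    grad_x_input,
    render_attribution,
)
from motse.model import build_batch, prepare_graph
from motse.molecules import N_FEATURES, parse_smiles


class _LinearSurrogate:
    """Model whose output is exactly linear in the atom features:
    y = sum_k u_k . w (identity message passing, sum pool)."""

    task_id = "linear"

    def __init__(self, w):
        self.w = np.asarray(w, dtype=np.float64).reshape(-1, 1)

    def output_tensor(self, X, A, offsets):
        return ad.segment_sum(ad.matmul(X, Tensor(self.w)), offsets)


def test_linear_surrogate_closed_form_hand_example():
    """Atoms u1=[1,0], u2=[0,1], weights w=[1,2], Nd=2:
    a_k = (1/2) sum_f w_f u_{k,f} = [0.5, 1.0]."""
    X = Tensor(np.array([[1.0, 0.0], [0.0, 1.0]]), requires_grad=True)
    out = ad.segment_sum(ad.matmul(X, Tensor(np.array([[1.0], [2.0]]))), np.array([0]))
    ad.total_sum(out).backward()
    a = (X.value * X.grad).mean(axis=1)
    assert np.allclose(a, [0.5, 1.0])


def test_linear_model_attribution_matches_closed_form():
    rng = np.random.default_rng(3)
    w = rng.normal(size=N_FEATURES)
    model = _LinearSurrogate(w)
    g = parse_smiles("CC(=O)NO")
    got = grad_x_input(model, g)
    from motse.molecules import featurize

    expected = (featurize(g) * w).mean(axis=1)
    assert np.allclose(got.scores, expected, atol=1e-14)


def test_zero_feature_rows_annihilate_attribution(tiny_model, probe20):
    """a_k = 0 whenever atom k's feature row is all zero, for any model."""
    g = probe20.molecules[0]
    X, A, off = build_batch([prepare_graph(g)])
    X = X.copy()
    X[0, :] = 0.0
    xt = Tensor(X, requires_grad=True)
    ad.total_sum(tiny_model.output_tensor(xt, A, off)).backward()
    a = (X * xt.grad).mean(axis=1)
    assert a[0] == 0.0


def _tie_free_molecule(model, molecules):
    """Pick a probe molecule whose max-pool argmax is unique per column,
    so central differences see the same subgradient as the tape."""
    from motse import autodiff as _ad

    for g in molecules:
        X, A, off = build_batch([prepare_graph(g)])
        h = Tensor(X)
        for l in range(model.config.n_gcn_layers):
            h = _ad.relu(_ad.matmul(_ad.spmm(A, h), model.params[f"gcn{l}.W"]))
        hv = h.value
        top2 = np.sort(hv, axis=0)[-2:, :]
        if (top2[1] - top2[0] > 1e-6).all():
            return g
    raise RuntimeError("no tie-free molecule in fixture set")


def test_attribution_matches_central_finite_differences(tiny_model, probe20):
    g = _tie_free_molecule(tiny_model, probe20.molecules)
    analytic = grad_x_input(tiny_model, g).scores
    X, A, off = build_batch([prepare_graph(g)])
    eps = 1e-3
    num_grad = np.zeros_like(X)
    for k in range(X.shape[0]):
        for f in range(X.shape[1]):
            Xp, Xm = X.copy(), X.copy()
            Xp[k, f] += eps
            Xm[k, f] -= eps
            num_grad[k, f] = (
                tiny_model.output_tensor(Tensor(Xp), A, off).value.sum()
                - tiny_model.output_tensor(Tensor(Xm), A, off).value.sum()
            ) / (2 * eps)
    numeric = (X * num_grad).mean(axis=1)
    scale = np.abs(numeric).max()
    assert np.allclose(analytic, numeric, atol=1e-3 * max(scale, 1e-6))


def test_scale_property_in_linear_model():
    """Doubling one feature of a linear model doubles that term's share."""
    w = np.full(N_FEATURES, 2.0)
    model = _LinearSurrogate(w)
    g = parse_smiles("CO")
    base = grad_x_input(model, g).scores
    X, A, off = build_batch([prepare_graph(g)])
    X2 = X.copy()
    X2[0] *= 2.0
    xt = Tensor(X2, requires_grad=True)
    ad.total_sum(model.output_tensor(xt, A, off)).backward()
    doubled = (X2 * xt.grad).mean(axis=1)
    assert doubled[0] == pytest.approx(2 * base[0])
    assert doubled[1] == pytest.approx(base[1])


def test_attribution_set_alignment_and_determinism(tiny_model, probe20):
    s1 = attribution_set(tiny_model, probe20)
    s2 = attribution_set(tiny_model, probe20)
    assert len(s1) == len(probe20)
    assert s1.probe_hash == probe20.hash
    for v1, v2, g in zip(s1.vectors, s2.vectors, probe20.molecules):
        assert len(v1) == g.n_atoms
        assert np.array_equal(v1.scores, v2.scores)


def test_attribution_set_batching_matches_per_molecule(tiny_model, probe20):
    batched = attribution_set(tiny_model, probe20, batch_size=7)
    for vec, g in zip(batched.vectors, probe20.molecules):
        single = grad_x_input(tiny_model, g)
        assert np.allclose(vec.scores, single.scores, atol=1e-12)


def test_attribution_json_round_trip(tiny_model, probe20):
    s = attribution_set(tiny_model, probe20)
    from motse.attribution import AttributionSet

    back = AttributionSet.from_json(s.to_json())
    assert back.task_id == s.task_id and back.probe_hash == s.probe_hash
    for a, b in zip(back.vectors, s.vectors):
        assert np.allclose(a.scores, b.scores)


def test_non_finite_scores_rejected():
    with pytest.raises(AttributionError):
        AttributionVector(np.array([1.0, np.nan]), "m")


def test_render_attribution_normalization_rules():
    g = parse_smiles("CO")
    rows = render_attribution(g, AttributionVector(np.array([1.0, 3.0]), "CO"))
    assert [r["normalized"] for r in rows] == [0.0, 1.0]
    assert [r["element"] for r in rows] == ["C", "O"]
    const = render_attribution(g, AttributionVector(np.array([2.0, 2.0]), "CO"))
    assert [r["normalized"] for r in const] == [0.5, 0.5]
    with pytest.raises(AttributionError):
        render_attribution(g, AttributionVector(np.array([1.0]), "CO"))
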