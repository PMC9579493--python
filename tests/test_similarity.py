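"""Similarity combination rules, matrix invariants, and similarity trees."""

import numpy as np
import pytest

from motse.attribution import AttributionSet, AttributionVector, attribution_set
from motse.mrsa import CorrelationVector, correlation_vector, embed_probe
from motse.similarity import (
    AlignmentError,
    DegenerateVectorError,
    SimilarityMatrix,
    TaskCollection,
    TaskEmbedding,
    attribution_similarity,
    combined_similarity,
    cosine_sim,
    mrsa_similarity,
    similarity_matrix,
    similarity_tree,
)


def _attr_set(vectors, task_id="t", probe_hash="h"):
    return AttributionSet(
        vectors=[AttributionVector(np.asarray(v, float), f"m{i}") for i, v in enumerate(vectors)],
        task_id=task_id,
        probe_hash=probe_hash,
    )


def test_cosine_reference_values():
    v = np.array([1.0, 2.0, -3.0])
    assert cosine_sim(v, v) == pytest.approx(1.0)
    assert cosine_sim([1, 0], [0, 1]) == pytest.approx(0.0)
    assert cosine_sim([1, 0], [-1, 0]) == pytest.approx(-1.0)
    with pytest.raises(DegenerateVectorError):
        cosine_sim([0.0, 0.0], [1.0, 2.0])


def test_cosine_matches_direct_formula_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(25):
        a, b = rng.normal(size=9), rng.normal(size=9)
        direct = (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert abs(cosine_sim(a, b) - direct) < 1e-12


def test_attribution_similarity_mean_of_per_molecule_cosines():
    Ai = _attr_set([[1.0, 0.0, 1.0], [1.0, 1.0]])
    # first molecule: cosine 0.6 against [0,1,...]-style vector; second: 1.0
    Aj = _attr_set([[0.6 * 2, 1.6, 0.6 * 2], [2.0, 2.0]])
    sA = attribution_similarity(Ai, Aj)
    c1 = cosine_sim([1, 0, 1], [1.2, 1.6, 1.2])
    assert sA == pytest.approx((c1 + 1.0) / 2)


def test_attribution_similarity_endpoints():
    Ai = _attr_set([[1.0, 2.0], [3.0, -1.0]])
    assert attribution_similarity(Ai, Ai) == pytest.approx(1.0)
    Aneg = _attr_set([[-1.0, -2.0], [-3.0, 1.0]])
    assert attribution_similarity(Ai, Aneg) == pytest.approx(-1.0)


def test_probe_hash_mismatch_is_an_alignment_error():
    Ai = _attr_set([[1.0, 2.0]], probe_hash="h1")
    Aj = _attr_set([[1.0, 2.0]], probe_hash="h2")
    with pytest.raises(AlignmentError):
        attribution_similarity(Ai, Aj)
    Ri = CorrelationVector(np.array([0.5]), "a", "h1", 2)
    Rj = CorrelationVector(np.array([0.5]), "b", "h2", 2)
    with pytest.raises(AlignmentError):
        mrsa_similarity(Ri, Rj)


def test_mrsa_similarity_equals_cosine_oracle():
    rng = np.random.default_rng(1)
    v1, v2 = rng.normal(size=10), rng.normal(size=10)
    Ri = CorrelationVector(np.clip(v1, -1, 1), "a", "h", 5)
    Rj = CorrelationVector(np.clip(v2, -1, 1), "b", "h", 5)
    assert mrsa_similarity(Ri, Rj) == pytest.approx(
        cosine_sim(Ri.values, Rj.values), abs=1e-15
    )


def test_combined_similarity_rules():
    assert combined_similarity(0.5, 0.9, 0.7) == pytest.approx(0.78)
    assert combined_similarity(0.3, 0.9, 0.0) == 0.3
    assert combined_similarity(0.3, 0.9, 1.0) == 0.9
    # default weighting factor is 0.7
    assert combined_similarity(0.0, 1.0) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        combined_similarity(0.1, 0.2, 1.5)


@pytest.fixture(scope="module")
def duplicate_collection(tiny_model, probe20):
    """One trained model registered as two tasks over the same probe."""
    def embed(task_id):
        attrs = attribution_set(tiny_model, probe20)
        attrs.task_id = task_id
        corr = correlation_vector(embed_probe(tiny_model, probe20))
        corr.task_id = task_id
        return TaskEmbedding(task_id=task_id, attributions=attrs, correlations=corr)

    return TaskCollection([embed("A"), embed("A_copy"), embed("B")])


def test_similarity_matrix_structure_and_self_similarity(duplicate_collection):
    S = similarity_matrix(duplicate_collection, lam=0.7)
    for M in (S.S_attr, S.S_mrsa, S.S):
        assert M.shape == (3, 3)
        assert np.allclose(M, M.T)
        assert np.all((M >= -1 - 1e-9) & (M <= 1 + 1e-9))
        assert np.allclose(np.diag(M), 1.0)
    # duplicated task: off-diagonal similarity 1 within 1e-6
    assert S.value("A", "A_copy") == pytest.approx(1.0, abs=1e-6)
    assert S.value("A", "A_copy", "attribution") == pytest.approx(1.0, abs=1e-6)
    assert S.value("A", "A_copy", "mrsa") == pytest.approx(1.0, abs=1e-6)


def test_matrix_entries_match_pairwise_ops(duplicate_collection):
    S = similarity_matrix(duplicate_collection, lam=0.7)
    e = duplicate_collection.embeddings
    sA = attribution_similarity(e[0].attributions, e[2].attributions)
    sR = mrsa_similarity(e[0].correlations, e[2].correlations)
    assert S.value("A", "B", "attribution") == pytest.approx(sA, abs=1e-15)
    assert S.value("A", "B", "mrsa") == pytest.approx(sR, abs=1e-15)
    assert S.value("A", "B") == pytest.approx(combined_similarity(sA, sR, 0.7), abs=1e-15)


def test_lambda_endpoint_identities(duplicate_collection):
    S0 = similarity_matrix(duplicate_collection, lam=0.0)
    S1 = similarity_matrix(duplicate_collection, lam=1.0)
    assert np.array_equal(S0.S, S0.S_attr) or np.allclose(S0.S, S0.S_attr, atol=0)
    off = ~np.eye(3, dtype=bool)
    assert (S0.S[off] == S0.S_attr[off]).all()
    assert (S1.S[off] == S1.S_mrsa[off]).all()


def _matrix(task_ids, S):
    S = np.asarray(S, float)
    return SimilarityMatrix(task_ids=task_ids, S_attr=S, S_mrsa=S, S=S, lam=0.7)


def test_tree_dominant_pair_merges_first():
    S = _matrix(["t1", "t2", "t3"], [[1, 0.95, 0.1], [0.95, 1, 0.1], [0.1, 0.1, 1]])
    tree = similarity_tree(S)
    # t1 and t2 are siblings under the lowest merge
    import skbio

    t = skbio.TreeNode.read([tree.newick])
    lca = t.lca(["t1", "t2"])
    assert {tip.name for tip in lca.tips()} == {"t1", "t2"}


def test_duplicate_tasks_merge_at_height_zero():
    S = _matrix(["a", "a2", "b"], [[1, 1.0, 0.2], [1.0, 1, 0.2], [0.2, 0.2, 1]])
    tree = similarity_tree(S)
    assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)


def test_newick_round_trips_through_a_standard_parser(duplicate_collection):
    import skbio

    S = similarity_matrix(duplicate_collection, lam=0.7)
    tree = similarity_tree(S)
    t = skbio.TreeNode.read([tree.newick])
    assert sorted(tip.name for tip in t.tips()) == sorted(S.task_ids)
    # root-to-leaf depth equals the final merge height for every leaf
    final_height = tree.linkage[-1, 2]
    for tip in t.tips():
        assert tip.accumulate_to_ancestor(t.root()) == pytest.approx(final_height, abs=1e-9)


def test_non_symmetric_matrix_rejected():
    with pytest.raises(ValueError):
        _matrix(["a", "b"], [[1.0, 0.5], [0.4, 1.0]])
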