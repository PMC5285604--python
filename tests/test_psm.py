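import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from psmforest import (cosine_psm, fit_unsupervised_forest, make_contrast_data, normalize_psm,
                       proximity, psm_matrix, rank_similar, terminal_node_ids)


# --- contrast construction --------------------------------------------------

def test_contrast_data_shape_and_labels(small_cohort):
    cohort, _ = small_cohort
    combined, labels = make_contrast_data(cohort.features, seed=0)
    assert len(combined) == 2 * cohort.n
    assert labels.sum() == cohort.n
    assert (labels[:cohort.n] == 0).all()


def test_contrast_constant_feature_identical():
    df = pd.DataFrame({"a": np.ones(50), "b": np.arange(50.0)})
    combined, labels = make_contrast_data(df, seed=1)
    assert (combined["a"] == 1.0).all()


def test_contrast_breaks_correlation():
    """Synthetic rows sample each marginal independently, so a strong real
    correlation vanishes in the contrast class."""
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 10_000)
    df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 0.1, 10_000)})
    combined, labels = make_contrast_data(df, seed=4)
    synth = combined[labels == 1]
    assert abs(np.corrcoef(synth["x"], synth["y"])[0, 1]) < 0.05
    real = combined[labels == 0]
    assert np.corrcoef(real["x"], real["y"])[0, 1] > 0.99


# --- forest and terminal nodes ----------------------------------------------

@pytest.fixture(scope="module")
def fitted_forest(small_cohort):
    cohort, _ = small_cohort
    return fit_unsupervised_forest(cohort, n_trees=40, seed=7)


def test_forest_tree_count(fitted_forest):
    assert fitted_forest.n_trees == 40
    assert len(fitted_forest.forest.estimators_) == 40


def test_forest_separates_structure_from_marginals(fitted_forest):
    # real dependence structure is learnable against marginal resampling
    assert fitted_forest.oob_error < 0.5


def test_terminal_nodes_deterministic_and_leafy(fitted_forest, small_cohort):
    cohort, _ = small_cohort
    row = cohort.features.iloc[[0]]
    a = terminal_node_ids(fitted_forest, row)
    b = terminal_node_ids(fitted_forest, row)
    assert np.array_equal(a, b)
    for t, est in enumerate(fitted_forest.forest.estimators_):
        node = a[0, t]
        assert est.tree_.children_left[node] == -1  # a leaf


def test_single_tree_proximity_binary(small_cohort):
    cohort, _ = small_cohort
    forest = fit_unsupervised_forest(cohort, n_trees=1, seed=3)
    nodes = terminal_node_ids(forest, cohort.features)
    prox = proximity(nodes, nodes)
    assert set(np.unique(prox)) <= {0, 1}


def test_degenerate_cohort_rejected(small_cohort):
    cohort, _ = small_cohort
    one_row = pd.concat([cohort.features.iloc[[0]]] * 30, ignore_index=True)
    with pytest.raises(ValueError, match="degenerate"):
        fit_unsupervised_forest(one_row, schema=cohort.schema, n_trees=5, seed=0)


# --- proximity counting -----------------------------------------------------

def brute_force_proximity(nodes_a, nodes_b):
    na, nb = len(nodes_a), len(nodes_b)
    T = nodes_a.shape[1]
    out = np.zeros((na, nb), dtype=int)
    for i in range(na):
        for j in range(nb):
            for t in range(T):
                out[i, j] += nodes_a[i, t] == nodes_b[j, t]
    return out


def test_proximity_matches_brute_force(rng):
    nodes_a = rng.integers(0, 6, size=(30, 25))
    nodes_b = rng.integers(0, 6, size=(40, 25))
    fast = proximity(nodes_a, nodes_b, row_block=7)
    assert np.array_equal(fast, brute_force_proximity(nodes_a, nodes_b))


def test_proximity_self_symmetric_diagonal_T(fitted_forest, small_cohort):
    cohort, _ = small_cohort
    nodes = terminal_node_ids(fitted_forest, cohort.features)
    prox = proximity(nodes, nodes)
    assert np.array_equal(prox, prox.T)
    assert (np.diag(prox) == fitted_forest.n_trees).all()


def test_proximity_single_leaf_all_ones():
    nodes = np.zeros((5, 1), dtype=int)
    assert (proximity(nodes, nodes) == 1).all()


def test_proximity_tree_count_mismatch():
    with pytest.raises(ValueError, match="tree counts"):
        proximity(np.zeros((3, 4), dtype=int), np.zeros((3, 5), dtype=int))


# --- normalization and ranking ----------------------------------------------

def test_normalize_arithmetic():
    w = normalize_psm(np.array([3, 1, 0]))
    assert w == pytest.approx([0.75, 0.25, 0.0])


def test_normalize_uniform_on_ties():
    w = normalize_psm(np.array([2, 2, 2, 2]))
    assert w == pytest.approx([0.25] * 4)


def test_normalize_zero_row_uniform_fallback():
    w = normalize_psm(np.zeros(4))
    assert w == pytest.approx([0.25] * 4)


def test_normalize_excludes_self():
    w = normalize_psm(np.array([10, 3, 1]), exclude=0)
    assert w[0] == 0.0
    assert w == pytest.approx([0.0, 0.75, 0.25])


def test_rank_similar_basic():
    assert list(rank_similar(np.array([0.5, 0.2, 0.3]), 2)) == [0, 2]


def test_rank_similar_all_and_ties():
    assert list(rank_similar(np.array([0.1, 0.1, 0.1, 0.1]), 3)) == [0, 1, 2]
    assert sorted(rank_similar(np.array([0.4, 0.1, 0.5]), 3)) == [0, 1, 2]
    with pytest.raises(ValueError):
        rank_similar(np.array([0.5, 0.5]), 3)


@given(st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=40))
@settings(deadline=None, max_examples=60)
def test_ranking_invariant_to_denominator(counts):
    """Ordering is identical whether counts are scaled by the row sum or by
    the tree count (positive-scalar invariance of the ranking)."""
    counts = np.array(counts, dtype=float)
    M = len(counts)
    by_rowsum = rank_similar(normalize_psm(counts + 1), M)  # +1 avoids the uniform fallback
    by_trees = rank_similar(normalize_psm(counts + 1, denominator="trees", n_trees=500), M)
    assert np.array_equal(by_rowsum, by_trees)


@given(st.lists(st.floats(min_value=0, max_value=1e6, allow_nan=False), min_size=1, max_size=50))
@settings(deadline=None, max_examples=60)
def test_psm_vector_sums_to_one(counts):
    w = normalize_psm(np.array(counts))
    assert w.sum() == pytest.approx(1.0, abs=1e-12)
    assert (w >= 0).all()


def test_psm_matrix_rows_sum_to_one(fitted_forest, small_cohort):
    cohort, _ = small_cohort
    nodes = terminal_node_ids(fitted_forest, cohort.features)
    W = psm_matrix(proximity(nodes, nodes), exclude_diagonal=True)
    assert np.allclose(W.sum(axis=1), 1.0, atol=1e-12)
    assert np.allclose(np.diag(W), 0.0)


# --- cosine comparator ------------------------------------------------------

def test_cosine_identical_row_is_maximal():
    X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    w = cosine_psm(np.array([1.0, 1.0]), X)
    assert np.argmax(w) == 2


def test_cosine_orthogonal_raw_zero():
    raw = cosine_psm(np.array([1.0, 0.0]), np.array([[0.0, 1.0]]), return_raw=True)
    assert raw[0] == pytest.approx(0.0, abs=1e-12)


def test_cosine_matches_direct_formula(rng):
    x = rng.normal(size=4)
    X = rng.normal(size=(3, 4))
    raw = cosine_psm(x, X, return_raw=True)
    expected = [float(x @ r / (np.linalg.norm(x) * np.linalg.norm(r))) for r in X]
    assert raw == pytest.approx(expected)
    w = cosine_psm(x, X)
    assert w.sum() == pytest.approx(1.0)
    assert np.array_equal(np.argsort(-w), np.argsort(-raw))


def test_cosine_zero_norm_uniform():
    w = cosine_psm(np.zeros(3), np.eye(3))
    assert w == pytest.approx([1 / 3] * 3)
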