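import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from psmforest import (ALL_DATA, CSRFConfig, PSMConfig, SweepGrid, auprc, auroc,
                       compare_best_vs_all, compute_fold_psm, make_folds, run_sweep,
                       summarize_ci)


# --- folds ------------------------------------------------------------------

def test_folds_partition_and_balance():
    plan = make_folds(100, k=10, seed=0)
    sizes = np.bincount(plan.assignment)
    assert (sizes == 10).all()
    plan17 = make_folds(17, k=10, seed=0)
    assert set(np.bincount(plan17.assignment)) <= {1, 2}


def test_folds_deterministic_and_seed_sensitive():
    a = make_folds(50, k=5, seed=3)
    b = make_folds(50, k=5, seed=3)
    c = make_folds(50, k=5, seed=4)
    assert np.array_equal(a.assignment, b.assignment)
    assert not np.array_equal(a.assignment, c.assignment)


def test_folds_too_few_patients():
    with pytest.raises(ValueError):
        make_folds(5, k=10, seed=0)


def test_stratified_folds_preserve_prevalence():
    y = np.array([1] * 20 + [0] * 80)
    plan = make_folds(100, k=10, seed=1, stratify_labels=y)
    for f in range(10):
        assert y[plan.assignment == f].sum() == 2


# --- AUROC ------------------------------------------------------------------

def test_auroc_perfect_and_constant():
    y = np.array([0, 0, 1, 1])
    assert auroc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
    assert auroc(np.full(4, 0.5), y) == 0.5


def test_auroc_pair_enumeration_example():
    # pairs: (0.9 vs 0.8) and (0.9 vs 0.6) concordant, (0.7 vs 0.8) discordant,
    # (0.7 vs 0.6) concordant -> 3/4
    assert auroc(np.array([0.9, 0.8, 0.7, 0.6]), np.array([1, 0, 1, 0])) == 0.75


def brute_force_auroc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_auprc(scores, labels):
    # average precision: sum of precision at each distinct threshold times the
    # recall increment it contributes
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    thresholds = np.unique(s)[::-1]
    ap, prev_recall = 0.0, 0.0
    n_pos = y.sum()
    for t in thresholds:
        sel = s >= t
        tp = y[sel].sum()
        precision = tp / sel.sum()
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def test_metrics_match_enumeration_oracles(rng):
    for _ in range(300):
        n = rng.integers(4, 21)
        y = rng.integers(0, 2, n)
        if y.min() == y.max():
            continue
        scores = rng.choice(np.linspace(0, 1, 6), size=n)  # coarse grid forces ties
        assert auroc(scores, y) == pytest.approx(brute_force_auroc(scores, y), abs=1e-12)
        assert auprc(scores, y) == pytest.approx(brute_force_auprc(scores, y), abs=1e-9)


def test_auroc_single_class_rejected():
    with pytest.raises(ValueError):
        auroc(np.array([0.1, 0.2]), np.array([1, 1]))
    with pytest.raises(ValueError):
        auprc(np.array([0.1, 0.2]), np.array([0, 0]))


@given(st.lists(st.tuples(st.floats(0, 1, allow_nan=False), st.integers(0, 1)),
                min_size=4, max_size=30))
@settings(deadline=None, max_examples=80)
def test_auroc_complementarity_and_monotone_invariance(pairs):
    scores = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if y.min() == y.max():
        return
    a = auroc(scores, y)
    assert a + auroc(scores, 1 - y) == pytest.approx(1.0, abs=1e-12)
    # strictly increasing transform leaves the ranking, hence AUROC, unchanged
    # (scaling by a power of two is exact in floats, so no ties are created)
    assert auroc(4.0 * scores, y) == pytest.approx(a, abs=1e-12)


def test_auprc_constant_scores_equal_prevalence():
    y = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
    assert auprc(np.full(10, 0.7), y) == pytest.approx(0.2)


def test_auprc_labels_as_scores_at_least_prevalence():
    y = np.array([1, 0, 1, 0, 0, 0])
    assert auprc(y.astype(float), y) >= y.mean()


# --- CI and t-test ----------------------------------------------------------

def test_ci_identical_values():
    assert summarize_ci(np.full(5, 0.8)) == pytest.approx((0.8, 0.8, 0.8))


def test_ci_two_point_closed_form():
    m, lo, hi = summarize_ci(np.array([0.0, 1.0]))
    hw = stats.t.ppf(0.975, 1) * np.std([0.0, 1.0], ddof=1) / np.sqrt(2)
    assert (m, hi - m) == pytest.approx((0.5, hw))


def test_ci_coverage_simulation(rng):
    """t-based 95% CI covers the true mean in ~95% of replicates."""
    covered = 0
    reps = 1000
    for _ in range(reps):
        vals = rng.normal(0.8, 0.01, 10)
        _, lo, hi = summarize_ci(vals)
        covered += lo <= 0.8 <= hi
    assert 0.93 <= covered / reps <= 0.97


def test_compare_identical_p_one():
    v = np.array([0.7, 0.8, 0.75])
    assert compare_best_vs_all(v, v) == 1.0


def test_compare_constant_shift_significant(rng):
    base = rng.normal(0.7, 0.001, 10)
    jitter = rng.normal(0, 1e-6, 10)
    assert compare_best_vs_all(base + 0.2 + jitter, base) < 0.001


def test_compare_constant_nonzero_diff_sign_fallback():
    a = np.array([0.5, 0.6, 0.7, 0.8])
    p = compare_best_vs_all(a + 0.1, a)
    assert p == pytest.approx(2 * 0.5**4)


def test_compare_type_one_error_calibrated(rng):
    """Under the null (both arms from the same distribution) the paired
    two-sided t test rejects at ~5% when alpha = 0.05."""
    reps, rejections = 4000, 0
    for _ in range(reps):
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 1, 10)
        rejections += compare_best_vs_all(a, b) < 0.05
    assert 0.04 <= rejections / reps <= 0.06


# --- run_sweep bookkeeping ---------------------------------------------------

@pytest.fixture(scope="module")
def sweep_setup(medium_cohort):
    cohort, _ = medium_cohort
    plan = make_folds(cohort.n, k=5, seed=2)
    cfg = PSMConfig(n_trees=30)
    weights = compute_fold_psm(cohort, plan, cfg, seed=5)
    return cohort, plan, cfg, weights


def test_sweep_record_count(sweep_setup):
    cohort, plan, cfg, weights = sweep_setup
    grid = SweepGrid("DC", (10, 50, 100), include_all_data=True)
    res = run_sweep(cohort, grid, cfg, plan, seed=5, fold_weights=weights)
    assert len(res.records) == (3 + 1) * plan.k
    assert set(res.records["M"]) == {10, 50, 100, ALL_DATA}
    assert res.records[["auroc", "auprc"]].le(1).all().all()
    assert res.records[["auroc", "auprc"]].ge(0).all().all()


def test_sweep_deterministic(sweep_setup):
    cohort, plan, cfg, weights = sweep_setup
    grid = SweepGrid("DC", (20, 80))
    r1 = run_sweep(cohort, grid, cfg, plan, seed=9, fold_weights=weights)
    r2 = run_sweep(cohort, grid, cfg, plan, seed=9, fold_weights=weights)
    assert r1.records.equals(r2.records)


def test_sweep_dc_all_data_is_chance(sweep_setup):
    """With M = all training data DC predicts one constant rate, so its
    AUROC is exactly 0.5 in every fold."""
    cohort, plan, cfg, weights = sweep_setup
    res = run_sweep(cohort, SweepGrid("DC", (50,)), cfg, plan, seed=5, fold_weights=weights)
    assert (res.fold_values("DC", ALL_DATA, "auroc") == 0.5).all()


def test_sweep_infeasible_M_rejected(sweep_setup):
    cohort, plan, cfg, weights = sweep_setup
    with pytest.raises(ValueError, match="exceed"):
        run_sweep(cohort, SweepGrid("DC", (cohort.n,)), cfg, plan, seed=5,
                  fold_weights=weights)


def test_csrf_grid_rejected():
    with pytest.raises(ValueError, match="soft"):
        SweepGrid("CSRF", (100, 200))


def test_csrf_runs_once_per_fold(sweep_setup):
    cohort, plan, cfg, weights = sweep_setup
    res = run_sweep(cohort, SweepGrid("CSRF", ()), cfg, plan, seed=5,
                    csrf_config=CSRFConfig(n_trees=15), max_test_per_fold=20,
                    fold_weights=weights)
    assert len(res.records) == plan.k
    assert set(res.records["M"]) == {ALL_DATA}
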