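"""Cross-validated evaluation harness: AUROC/AUPRC, the neighborhood-size
(M) sweep per model family, CI summaries, and best-vs-all significance tests.

The protocol is 10-fold cross-validation. Within each fold an unsupervised
proximity forest supplies PSM weights from every test patient to every
training patient; each model family is then trained per test patient on the
M most similar training cases for every M on that family's grid (plus an
"all training data" condition), the fold's test patients are scored, and one
AUROC and one AUPRC are recorded per (family, M, fold). CSRF takes no M grid
— it is soft thresholding — and runs once per fold. "Best" performance is
the grid point with the maximum mean metric; it is compared against the
all-data condition with a two-sided t test over folds (paired by default,
since both conditions share folds; the unpaired variant is also computed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score

from ._rng import stage_rng, stage_seed
from .cohort import CohortTable
from .csrf import CSRFConfig, fit_csrf
from .models import LocalTrainingSet, predict_risk, train_local_model
from .psm import fit_unsupervised_forest, normalize_psm, proximity, terminal_node_ids

__all__ = [
    "FoldPlan",
    "SweepGrid",
    "PSMConfig",
    "SweepResult",
    "ALL_DATA",
    "make_folds",
    "auroc",
    "auprc",
    "summarize_ci",
    "compare_best_vs_all",
    "compute_fold_psm",
    "run_sweep",
    "best_vs_all",
]

log = logging.getLogger(__name__)

#: sentinel M value for the "all training data" condition
ALL_DATA = -1


# ---------------------------------------------------------------------------
# folds and metrics
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # fold id per patient, 0..k-1
    seed: int = 0

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        sizes = np.bincount(self.assignment, minlength=self.k)
        if len(sizes) != self.k or sizes.max() - sizes.min() > 1 or sizes.min() == 0:
            raise ValueError("folds must partition patients with sizes differing by <= 1")

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        test = np.flatnonzero(self.assignment == fold)
        train = np.flatnonzero(self.assignment != fold)
        return train, test


def make_folds(n: int, k: int = 10, seed: int = 0,
               stratify_labels: np.ndarray | None = None) -> FoldPlan:
    """Random k-fold partition with near-equal sizes (unstratified by default)."""
    if n < k:
        raise ValueError(f"cannot split n={n} patients into k={k} folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify_labels is None:
        perm = rng.permutation(n)
        assignment[perm] = np.arange(n) % k
    else:
        labels = np.asarray(stratify_labels)
        offset = 0
        for lv in np.unique(labels):
            idx = np.flatnonzero(labels == lv)
            perm = rng.permutation(idx)
            assignment[perm] = (np.arange(len(idx)) + offset) % k
            offset += len(idx)
    return FoldPlan(k=k, assignment=assignment, seed=seed)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUROC: P(random death outranks random survivor), ties 0.5."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: both outcome classes must be present")
    ranks = stats.rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Average-precision AUPRC (tie blocks collapse to a single threshold)."""
    y = np.asarray(labels, dtype=int)
    if y.sum() == 0:
        raise ValueError("AUPRC undefined: no positive cases")
    return float(average_precision_score(y, np.asarray(scores, dtype=float)))


def summarize_ci(fold_values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-based CI over fold values: mean +/- t_{a,k-1} * sd / sqrt(k)."""
    v = np.asarray(fold_values, dtype=float)
    k = v.size
    if k < 2:
        raise ValueError("need at least 2 fold values for a CI")
    m = float(v.mean())
    hw = float(stats.t.ppf(0.5 + level / 2, k - 1) * v.std(ddof=1) / np.sqrt(k))
    return m, m - hw, m + hw


def compare_best_vs_all(fold_best: np.ndarray, fold_all: np.ndarray,
                        paired: bool = True) -> float:
    """Two-sided t test between best-M and all-data fold metrics.

    Paired by fold by default. Zero-variance differences are handled
    explicitly: all-zero differences give p = 1; a constant nonzero
    difference falls back to an exact sign test.
    """
    a = np.asarray(fold_best, dtype=float)
    b = np.asarray(fold_all, dtype=float)
    if a.shape != b.shape:
        raise ValueError("fold vectors must have equal length")
    if not paired:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(stats.ttest_ind(a, b).pvalue)
    d = a - b
    if np.allclose(d, 0.0):
        return 1.0
    if np.isclose(d.std(ddof=1), 0.0):
        nonzero = d[d != 0]
        return float(stats.binomtest(int((nonzero > 0).sum()), len(nonzero), 0.5).pvalue)
    with warnings.catch_warnings():
        # one zero-variance arm triggers a harmless precision warning inside scipy
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(stats.ttest_rel(a, b).pvalue)


# ---------------------------------------------------------------------------
# the M-sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepGrid:
    """Neighborhood sizes evaluated for one family; CSRF takes an empty grid."""

    family: str
    M_values: tuple[int, ...] = ()
    include_all_data: bool = True

    def __post_init__(self) -> None:
        self.family = self.family.upper()
        M = tuple(int(m) for m in self.M_values)
        if any(m2 <= m1 for m1, m2 in zip(M, M[1:])) or any(m < 1 for m in M):
            raise ValueError("M_values must be strictly increasing positive integers")
        self.M_values = M
        if self.family == "CSRF" and self.M_values:
            raise ValueError("CSRF is soft thresholding; an M grid does not apply")


@dataclass
class PSMConfig:
    """Unsupervised proximity forest parameters and scope.

    ``scope='per_fold'`` (default) grows the forest within each fold on the
    union of that fold's training and test features — labels are never used,
    so no outcome leakage occurs; ``'global'`` grows one forest on the whole
    cohort before cross-validation (the literal all-data reading, with
    feature sharing across folds).
    """

    n_trees: int = 500
    nodesize: int = 5
    mtry: int | None = None  # None -> all encoded predictors
    scope: str = "per_fold"
    denominator: str = "rowsum"

    def __post_init__(self) -> None:
        if self.scope not in ("per_fold", "global"):
            raise ValueError("scope must be 'per_fold' or 'global'")


@dataclass
class SweepResult:
    """Per-(family, M, fold) metric records; M = -1 denotes all training data."""

    records: pd.DataFrame

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for (family, M), grp in self.records.groupby(["family", "M"], sort=True):
            for metric in ("auroc", "auprc"):
                m, lo, hi = summarize_ci(grp[metric].to_numpy(), level=level)
                rows.append({"family": family, "M": M, "metric": metric,
                             "mean": m, "lower": lo, "upper": hi})
        return pd.DataFrame(rows)

    def fold_values(self, family: str, M: int, metric: str = "auroc") -> np.ndarray:
        sel = self.records[(self.records["family"] == family.upper())
                           & (self.records["M"] == M)]
        return sel.sort_values("fold")[metric].to_numpy()

    def concat(self, other: "SweepResult") -> "SweepResult":
        return SweepResult(pd.concat([self.records, other.records], ignore_index=True))


def _psm_rows(forest, train_feats, test_feats, denominator):
    nodes_train = terminal_node_ids(forest, train_feats)
    nodes_test = terminal_node_ids(forest, test_feats)
    prox = proximity(nodes_test, nodes_train)
    T = nodes_train.shape[1]
    return np.vstack([
        normalize_psm(prox[i], denominator="rowsum")
        if denominator == "rowsum"
        else normalize_psm(prox[i], denominator="trees", n_trees=T)
        for i in range(prox.shape[0])
    ])


def _ranked_neighbors(weights_row: np.ndarray) -> np.ndarray:
    # full descending order, ties by ascending training position
    return np.lexsort((np.arange(weights_row.size), -weights_row))


def compute_fold_psm(
    cohort: CohortTable,
    fold_plan: FoldPlan,
    psm_config: PSMConfig | None = None,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-fold PSM weight matrices (test rows x training rows).

    Growing the unsupervised forest dominates sweep runtime, and its weights
    depend only on (cohort, folds, PSM config, seed) — never on the model
    family — so computing them once and passing the result to several
    :func:`run_sweep` calls gives identical records at a fraction of the cost.
    """
    psm_config = psm_config or PSMConfig()
    global_forest = None
    if psm_config.scope == "global":
        global_forest = fit_unsupervised_forest(
            cohort, n_trees=psm_config.n_trees, mtry=psm_config.mtry,
            nodesize=psm_config.nodesize, seed=stage_seed(seed, "psm-global"),
        )
    feats = cohort.features
    out = []
    for f in range(fold_plan.k):
        train_idx, test_idx = fold_plan.split(f)
        train_feats = feats.iloc[train_idx].reset_index(drop=True)
        test_feats = feats.iloc[test_idx].reset_index(drop=True)
        forest = global_forest
        if forest is None:
            fold_feats = pd.concat([train_feats, test_feats], ignore_index=True)
            forest = fit_unsupervised_forest(
                fold_feats, schema=cohort.schema, n_trees=psm_config.n_trees,
                mtry=psm_config.mtry, nodesize=psm_config.nodesize,
                seed=stage_seed(seed, f"psm-fold{f}"),
            )
        out.append(_psm_rows(forest, train_feats, test_feats, psm_config.denominator))
    return out


def run_sweep(
    cohort: CohortTable,
    grid: SweepGrid,
    psm_config: PSMConfig | None = None,
    fold_plan: FoldPlan | None = None,
    seed: int = 0,
    rf_trees: int = 500,
    csrf_config: CSRFConfig | None = None,
    max_test_per_fold: int | None = None,
    fold_weights: list[np.ndarray] | None = None,
) -> SweepResult:
    """Run one family's cross-validated M-sweep and return per-fold metrics.

    ``max_test_per_fold`` optionally caps how many test patients are scored
    per fold (a deterministic random subset); fold metrics are then computed
    on that subset. This trades metric precision for runtime and is the knob
    used to keep per-patient forest families affordable. ``fold_weights``
    accepts precomputed PSM matrices from :func:`compute_fold_psm` so several
    families can share one set of proximity forests.
    """
    psm_config = psm_config or PSMConfig()
    fold_plan = fold_plan or make_folds(cohort.n, seed=stage_seed(seed, "folds"))
    family = grid.family
    y = cohort.outcome
    feats = cohort.features

    n_train_min = cohort.n - int(np.ceil(cohort.n / fold_plan.k))
    bad = [m for m in grid.M_values if m > n_train_min]
    if bad:
        raise ValueError(f"M values {bad} exceed the training-fold size {n_train_min}")

    if fold_weights is None:
        fold_weights = compute_fold_psm(cohort, fold_plan, psm_config, seed=seed)
    if len(fold_weights) != fold_plan.k:
        raise ValueError("fold_weights must contain one matrix per fold")

    conditions = list(grid.M_values)
    if grid.include_all_data or family == "CSRF":
        conditions.append(ALL_DATA)

    records = []
    for f in range(fold_plan.k):
        train_idx, test_idx = fold_plan.split(f)
        y_tr, y_te = y[train_idx], y[test_idx]
        train_feats = feats.iloc[train_idx].reset_index(drop=True)
        test_feats = feats.iloc[test_idx].reset_index(drop=True)
        W = fold_weights[f]

        scored = np.arange(len(test_idx))
        if max_test_per_fold is not None and max_test_per_fold < len(scored):
            # outcome-stratified subsample so both classes stay represented
            rng = stage_rng(seed, f"subsample-fold{f}")
            pos = np.flatnonzero(y_te == 1)
            neg = np.flatnonzero(y_te == 0)
            n_pos = min(len(pos), max(1, int(round(max_test_per_fold * len(pos) / len(y_te)))))
            n_neg = max_test_per_fold - n_pos
            scored = np.sort(np.concatenate([
                rng.choice(pos, size=n_pos, replace=False),
                rng.choice(neg, size=min(n_neg, len(neg)), replace=False),
            ]))
        labels = y_te[scored]
        if labels.min() == labels.max():
            raise ValueError(f"fold {f} has a single outcome class among scored patients")

        scores = _score_fold(
            family, conditions, W, scored, cohort, train_idx, train_feats, test_feats,
            y_tr, seed, f, rf_trees, csrf_config,
        )
        for cond in conditions:
            records.append({
                "family": family, "M": cond, "fold": f,
                "auroc": auroc(scores[cond], labels),
                "auprc": auprc(scores[cond], labels),
            })
        log.info("fold %d/%d done for %s", f + 1, fold_plan.k, family)
    return SweepResult(pd.DataFrame(records))


def _score_fold(family, conditions, W, scored, cohort, train_idx, train_feats,
                test_feats, y_tr, seed, fold, rf_trees, csrf_config):
    """Scores per condition for the scored test patients of one fold."""
    n_train = len(train_idx)
    scores: dict[int, np.ndarray] = {c: np.empty(len(scored)) for c in conditions}

    if family == "DC":
        for si, i in enumerate(scored):
            order = _ranked_neighbors(W[i])
            cs = np.cumsum(y_tr[order])
            for cond in conditions:
                m = n_train if cond == ALL_DATA else cond
                scores[cond][si] = cs[m - 1] / m
        return scores

    if family == "CSRF":
        cfg = csrf_config or CSRFConfig()
        train_cohort = cohort.take(train_idx)
        for si, i in enumerate(scored):
            local_cfg = CSRFConfig(
                n_trees=cfg.n_trees, nodesize=cfg.nodesize, mtry=cfg.mtry,
                seed=stage_seed(seed, f"csrf-f{fold}-i{i}"),
            )
            model = fit_csrf(train_cohort, W[i], local_cfg)
            scores[ALL_DATA][si] = model.predict(test_feats.iloc[[i]])[0]
        return scores

    # LR / DT / RF: per-patient local models; the all-data (and M == n_train)
    # condition is index-independent, so it is fitted once per fold.
    shared: dict[int, object] = {}
    for cond in conditions:
        m = n_train if cond == ALL_DATA else cond
        if m == n_train and m not in shared:
            ts = LocalTrainingSet(train_feats, y_tr, cohort.schema)
            shared[m] = train_local_model(
                family, ts, seed=stage_seed(seed, f"{family}-f{fold}-all"),
                rf_trees=rf_trees,
            )
    for si, i in enumerate(scored):
        order = None
        row = test_feats.iloc[[i]]
        for cond in conditions:
            m = n_train if cond == ALL_DATA else cond
            if m in shared:
                scores[cond][si] = predict_risk(shared[m], row)[0]
                continue
            if order is None:
                order = _ranked_neighbors(W[i])
            nbr = order[:m]
            ts = LocalTrainingSet(
                train_feats.iloc[nbr].reset_index(drop=True), y_tr[nbr],
                cohort.schema, index_id=int(i),
            )
            model = train_local_model(
                family, ts, seed=stage_seed(seed, f"{family}-f{fold}-i{i}-M{m}"),
                rf_trees=rf_trees,
            )
            scores[cond][si] = predict_risk(model, row)[0]
    return scores


def best_vs_all(result: SweepResult, family: str, metric: str = "auroc") -> dict:
    """Best grid point (max mean metric) vs the all-data condition.

    Returns the best M, the fold means, and paired/unpaired two-sided t-test
    p-values for the best-vs-all comparison.
    """
    family = family.upper()
    recs = result.records[result.records["family"] == family]
    grid_Ms = sorted(m for m in recs["M"].unique() if m != ALL_DATA)
    if not grid_Ms or ALL_DATA not in recs["M"].unique():
        raise ValueError("best_vs_all needs both grid and all-data conditions")
    means = {m: recs[recs["M"] == m][metric].mean() for m in grid_Ms}
    best_M = max(means, key=lambda m: (means[m], -m))
    fb = result.fold_values(family, best_M, metric)
    fa = result.fold_values(family, ALL_DATA, metric)
    return {
        "family": family,
        "metric": metric,
        "best_M": int(best_M),
        "mean_best": float(np.mean(fb)),
        "mean_all": float(np.mean(fa)),
        "p_paired": compare_best_vs_all(fb, fa, paired=True),
        "p_unpaired": compare_best_vs_all(fb, fa, paired=False),
    }
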