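"""Random-forest proximity patient similarity metric (PSM).

A forest is grown in unsupervised mode: the real rows are contrasted against
an equal number of synthetic rows whose features are sampled independently
from each feature's empirical marginal, so the forest learns the dependence
structure of the real data. The proximity Prox_ij between two patients is the
number of trees in which both land in the same terminal node; one patient's
proximities over the training set, normalized to sum to one, are the PSM
weights used for hard-threshold neighbor selection and for CSRF bootstrap
weighting. Dividing by the row sum rather than the tree count changes none of
the induced rankings (positive-scalar invariance); the row-sum denominator is
the default because bootstrap weights must form a probability distribution,
and the alternative is exposed via ``denominator="trees"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import CohortTable, FeatureEncoder, Standardizer
from .schema import FeatureSchema

__all__ = [
    "UnsupervisedForest",
    "make_contrast_data",
    "fit_unsupervised_forest",
    "terminal_node_ids",
    "proximity",
    "normalize_psm",
    "psm_matrix",
    "rank_similar",
    "cosine_psm",
]

log = logging.getLogger(__name__)


def make_contrast_data(features: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Two-class contrast table: real rows (class 0) vs marginal-sampled rows (class 1).

    Each synthetic feature column is an independent resample (with
    replacement) of that column's empirical values, which preserves every
    marginal but destroys the joint dependence the forest is asked to detect.
    """
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 rows to build contrast data")
    rng = np.random.default_rng(seed)
    synth = pd.DataFrame(
        {c: features[c].to_numpy()[rng.integers(0, n, size=n)] for c in features.columns}
    )
    combined = pd.concat([features, synth], ignore_index=True)
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    return combined, labels


@dataclass
class UnsupervisedForest:
    """Contrast-trained forest used only through its terminal-node geometry."""

    forest: RandomForestClassifier
    encoder: FeatureEncoder
    n_trees: int
    mtry: int
    nodesize: int
    seed: int
    oob_error: float

    def apply(self, features: pd.DataFrame) -> np.ndarray:
        return self.forest.apply(self.encoder.transform(features))


def fit_unsupervised_forest(
    cohort: CohortTable | pd.DataFrame,
    schema: FeatureSchema | None = None,
    n_trees: int = 500,
    mtry: int | None = None,
    nodesize: int = 5,
    seed: int = 0,
) -> UnsupervisedForest:
    """Grow the unsupervised proximity forest.

    Defaults follow the PSM parameterization: ``mtry`` equal to the full
    encoded predictor count, terminal nodes of at least 5 cases, 500 trees.
    Outcome labels are never seen; only the feature geometry matters, so the
    forest may be grown on any set of schema-conforming rows (e.g. the union
    of a fold's training and test features).
    """
    if isinstance(cohort, CohortTable):
        features, schema = cohort.features, cohort.schema
    else:
        if schema is None:
            raise ValueError("schema is required when passing a bare feature frame")
        features = cohort
    if len(features) < 2 * nodesize:
        raise ValueError("cohort too small for the requested nodesize")
    if features.drop_duplicates().shape[0] < 2:
        raise ValueError("degenerate cohort: fewer than 2 unique rows")
    encoder = FeatureEncoder(schema)
    contrast, labels = make_contrast_data(features, seed=seed)
    X = encoder.transform(contrast)
    mtry = encoder.n_features if mtry is None else int(mtry)
    use_oob = n_trees >= 20  # OOB coverage is unreliable for tiny forests
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=None if mtry >= encoder.n_features else mtry,
        min_samples_leaf=nodesize,
        oob_score=use_oob,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, labels)
    oob_error = 1.0 - float(forest.oob_score_) if use_oob else float("nan")
    log.info("unsupervised forest: %d trees, mtry=%d, OOB contrast error %.3f",
             n_trees, mtry, oob_error)
    return UnsupervisedForest(forest, encoder, n_trees, mtry, nodesize, seed, oob_error)


def terminal_node_ids(forest: UnsupervisedForest, features: pd.DataFrame) -> np.ndarray:
    """Terminal-node id of every row in every tree, shape (n_rows, T)."""
    return forest.apply(features)


def proximity(nodes_index: np.ndarray, nodes_ref: np.ndarray, row_block: int = 512) -> np.ndarray:
    """Count per-tree terminal-node co-occurrences, Prox_ij in [0, T].

    Computed in row blocks so only (block x n_ref) scratch is live at a time;
    the full index-by-reference matrix is returned as int32.
    """
    nodes_index = np.asarray(nodes_index)
    nodes_ref = np.asarray(nodes_ref)
    if nodes_index.ndim != 2 or nodes_ref.ndim != 2:
        raise ValueError("node-id inputs must be 2-D (rows x trees)")
    if nodes_index.shape[1] != nodes_ref.shape[1]:
        raise ValueError("tree counts differ between index and reference node ids")
    T = nodes_index.shape[1]
    out = np.zeros((nodes_index.shape[0], nodes_ref.shape[0]), dtype=np.int32)
    for start in range(0, nodes_index.shape[0], row_block):
        blk = nodes_index[start:start + row_block]
        acc = np.zeros((blk.shape[0], nodes_ref.shape[0]), dtype=np.int32)
        for t in range(T):
            acc += blk[:, t, None] == nodes_ref[None, :, t]
        out[start:start + row_block] = acc
    return out


def normalize_psm(prox_row: np.ndarray, exclude: int | None = None,
                  denominator: str = "rowsum", n_trees: int | None = None) -> np.ndarray:
    """Turn one patient's proximity counts into similarity weights.

    ``denominator="rowsum"`` yields weights summing to 1 (a sampling
    distribution); ``"trees"`` divides by the tree count instead, which
    preserves every ranking but not the unit sum. An all-zero row falls back
    to uniform weights (logged) so downstream selection stays well defined.
    """
    row = np.asarray(prox_row, dtype=float).copy()
    if row.size == 0:
        raise ValueError("empty proximity row")
    if exclude is not None:
        row[exclude] = 0.0
    if denominator == "trees":
        if n_trees is None:
            raise ValueError("denominator='trees' requires n_trees")
        return row / float(n_trees)
    total = row.sum()
    if total <= 0:
        log.warning("all-zero proximity row: falling back to uniform weights")
        m = row.size if exclude is None else row.size - 1
        out = np.full(row.size, 1.0 / m)
        if exclude is not None:
            out[exclude] = 0.0
        return out
    return row / total


def psm_matrix(prox: np.ndarray, exclude_diagonal: bool = False) -> np.ndarray:
    """Row-normalize a whole proximity block into PSM weight rows."""
    prox = np.asarray(prox)
    return np.vstack([
        normalize_psm(prox[i], exclude=i if exclude_diagonal else None)
        for i in range(prox.shape[0])
    ])


def rank_similar(weights: np.ndarray, M: int) -> np.ndarray:
    """Indices of the M largest weights, descending; ties by ascending index."""
    weights = np.asarray(weights, dtype=float)
    if not 1 <= M <= weights.size:
        raise ValueError(f"M={M} out of range 1..{weights.size}")
    order = np.lexsort((np.arange(weights.size), -weights))
    return order[:M]


def cosine_psm(index_row: np.ndarray, training_rows: np.ndarray,
               return_raw: bool = False) -> np.ndarray:
    """Cosine-similarity comparator PSM over z-scaled encoded features.

    Raw cosines are shifted by +1 onto [0, 2] and normalized to sum to 1 for
    interface parity with the proximity PSM. A zero-norm vector contributes
    raw similarity 0 everywhere (uniform weights after normalization).
    """
    x = np.asarray(index_row, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(training_rows, dtype=float))
    xn = np.linalg.norm(x)
    Xn = np.linalg.norm(X, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        raw = (X @ x) / (Xn * xn)
    raw = np.where(np.isfinite(raw), raw, 0.0)
    if return_raw:
        return raw
    shifted = raw + 1.0
    total = shifted.sum()
    if total <= 0:
        return np.full(len(X), 1.0 / len(X))
    return shifted / total


def cosine_encode(features: pd.DataFrame, schema: FeatureSchema,
                  scaler: Standardizer | None = None) -> tuple[np.ndarray, Standardizer]:
    """One-hot + z-scale features for the cosine comparator (train-set statistics)."""
    X = FeatureEncoder(schema).transform(features)
    if scaler is None:
        scaler = Standardizer().fit(X)
    return scaler.transform(X), scaler
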