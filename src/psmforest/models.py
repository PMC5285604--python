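"""Personalized (per-index-patient) risk models trained on similar neighbors.

Four families share one contract — train on the M most similar training
patients, return a death probability for the index patient:

* DC (death counting): the neighborhood's empirical death fraction; ignores
  features. With M equal to all training data this degenerates to the overall
  training mortality rate.
* LR: maximum-likelihood logistic regression (no regularization).
* DT: a recursive-partitioning classification tree with conservative
  stopping rules in the spirit of classic CART defaults (minimum 20 cases to
  split, 7 per leaf).
* RF: a bootstrap forest with the conventional defaults, mtry =
  floor(sqrt(p)) and 500 trees.

Small homogeneous neighborhoods routinely contain single-level categorical
predictors or a single outcome class; constant predictors are dropped before
fitting and single-class outcomes short-circuit to a constant-risk model, so
every neighborhood yields a usable prediction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeClassifier

from .cohort import FeatureEncoder
from .forest import BootstrapForest
from .schema import FeatureSchema

__all__ = [
    "LocalTrainingSet",
    "RiskModel",
    "train_death_counting",
    "drop_degenerate_predictors",
    "train_local_model",
    "predict_risk",
]

log = logging.getLogger(__name__)

FAMILIES = ("DC", "LR", "DT", "RF")


@dataclass
class LocalTrainingSet:
    """The M nearest training records serving one index patient."""

    features: pd.DataFrame
    outcomes: np.ndarray
    schema: FeatureSchema
    index_id: int | None = None

    def __post_init__(self) -> None:
        self.outcomes = np.asarray(self.outcomes, dtype=int)
        if len(self.features) != len(self.outcomes):
            raise ValueError("features and outcomes length mismatch")
        if len(self.features) < 1:
            raise ValueError("local training set must contain at least one patient")

    @property
    def M(self) -> int:
        return len(self.features)


@dataclass
class RiskModel:
    family: str
    constant_risk: float | None = None
    estimator: object | None = None
    encoder: FeatureEncoder | None = None
    predictors: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return predict_risk(self, features)


def train_death_counting(outcomes: np.ndarray) -> RiskModel:
    """Risk = empirical death fraction among the neighborhood; no features used."""
    y = np.asarray(outcomes, dtype=int)
    if y.size == 0:
        raise ValueError("death counting needs at least one outcome")
    return RiskModel(family="DC", constant_risk=float(y.sum()) / y.size)


def drop_degenerate_predictors(ts: LocalTrainingSet) -> tuple[LocalTrainingSet, list[str]]:
    """Remove predictors constant across the neighborhood (they carry no signal
    and, for single-level categoricals, break factor-style fitting)."""
    dropped: list[str] = []
    for e in ts.schema.entries:
        col = ts.features[e.name]
        if col.nunique(dropna=False) <= 1:
            dropped.append(e.name)
    if not dropped:
        return ts, []
    keep = [n for n in ts.schema.names if n not in dropped]
    log.debug("dropped %d constant predictor(s): %s", len(dropped), dropped)
    reduced = LocalTrainingSet(
        features=ts.features[keep],
        outcomes=ts.outcomes,
        schema=ts.schema.subset(keep),
        index_id=ts.index_id,
    )
    return reduced, dropped


def _fit_lr(X: np.ndarray, y: np.ndarray) -> LogisticRegression | None:
    # C=inf -> unregularized maximum-likelihood fit
    lr = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=500)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        try:
            lr.fit(X, y)
        except Exception:  # noqa: BLE001 - any fit failure falls back to constant risk
            return None
    if not np.isfinite(lr.coef_).all() or not np.isfinite(lr.intercept_).all():
        return None
    return lr


def train_local_model(family: str, ts: LocalTrainingSet, seed: int = 0,
                      rf_trees: int = 500) -> RiskModel:
    """Fit one model family on a local training set.

    Constant predictors are dropped first. Single-class outcomes (or an empty
    predictor set) return a constant-risk model equal to the neighborhood
    death rate without attempting a fit; an LR fit that fails or produces
    non-finite coefficients (separation) falls back the same way, logged.
    """
    family = family.upper()
    if family == "DC":
        return train_death_counting(ts.outcomes)
    if family not in ("LR", "DT", "RF"):
        raise ValueError(f"unknown model family {family!r}")

    reduced, dropped = drop_degenerate_predictors(ts)
    rate = float(reduced.outcomes.mean())
    if reduced.outcomes.min() == reduced.outcomes.max() or reduced.schema.n_predictors == 0:
        return RiskModel(family=family, constant_risk=rate, dropped=dropped)

    encoder = FeatureEncoder(reduced.schema)
    X = encoder.transform(reduced.features)
    y = reduced.outcomes

    if family == "LR":
        est = _fit_lr(X, y)
        if est is None:
            log.info("LR fit failed (separation/non-convergence); constant-risk fallback")
            return RiskModel(family=family, constant_risk=rate, dropped=dropped)
    elif family == "DT":
        est = DecisionTreeClassifier(
            min_samples_split=20, min_samples_leaf=7, random_state=seed,
        ).fit(X, y)
    else:  # RF
        est = BootstrapForest(n_trees=rf_trees, nodesize=1, seed=seed).fit(X, y)

    return RiskModel(
        family=family,
        estimator=est,
        encoder=encoder,
        predictors=reduced.schema.names,
        dropped=dropped,
    )


def predict_risk(model: RiskModel, features: pd.DataFrame) -> np.ndarray:
    """Death probability in [0,1] for each row; dropped predictors are ignored."""
    n = len(features)
    if model.constant_risk is not None:
        return np.full(n, model.constant_risk)
    X = model.encoder.transform(features)
    est = model.estimator
    if isinstance(est, BootstrapForest):
        risk = est.predict_risk(X)
    elif isinstance(est, LogisticRegression):
        risk = est.predict_proba(X)[:, 1]
    elif isinstance(est, DecisionTreeClassifier):
        pos = list(est.classes_).index(1)
        risk = est.predict_proba(X)[:, pos]
    else:
        raise TypeError(f"unsupported estimator {type(est)!r}")
    return np.clip(risk, 0.0, 1.0)
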