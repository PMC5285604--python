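"""Case-specific random forest (CSRF).

Instead of hard-thresholding to the M nearest neighbors, a CSRF keeps the
entire training fold and personalizes through the bootstrap: each of the T
trees is grown on n_train draws with replacement in which training patient j
is drawn with probability equal to the index patient's PSM weight on j. This
is soft thresholding — dissimilar patients are down-weighted, not discarded —
so a neighborhood-size sweep does not apply.

Defaults: 500 trees, terminal nodes of size 1, mtry = floor(sqrt(p)).
With uniform weights the CSRF is exactly a standard bootstrap forest (same
sampling machinery, same seed, same trees).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortTable, FeatureEncoder
from .forest import BootstrapForest, weighted_bootstrap
from .models import RiskModel

__all__ = ["CSRFConfig", "fit_csrf", "weighted_bootstrap"]


@dataclass
class CSRFConfig:
    n_trees: int = 500
    nodesize: int = 1
    mtry: int | None = None  # None -> floor(sqrt(p)) at fit time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


def fit_csrf(train: CohortTable, weights: np.ndarray,
             config: CSRFConfig | None = None) -> RiskModel:
    """Grow a case-specific forest for one index patient.

    ``weights`` is that patient's PSM vector over the training rows (must sum
    to 1 and align with ``train.patient_index``). If every weighted bootstrap
    sample is single-class the model degenerates to a constant-risk vote.
    """
    config = config or CSRFConfig()
    w = np.asarray(weights, dtype=float)
    if w.shape != (train.n,):
        raise ValueError("weights must align one-to-one with training rows")
    encoder = FeatureEncoder(train.schema)
    X = encoder.transform(train.features)
    y = train.outcome
    forest = BootstrapForest(
        n_trees=config.n_trees, mtry=config.mtry, nodesize=config.nodesize, seed=config.seed
    ).fit(X, y, weights=w)
    if all(isinstance(t, int) for t in forest._trees):
        votes = float(np.mean([t for t in forest._trees]))
        return RiskModel(family="CSRF", constant_risk=votes)
    return RiskModel(family="CSRF", estimator=forest, encoder=encoder,
                     predictors=train.schema.names)
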