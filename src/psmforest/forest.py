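"""Bootstrap forest with an explicit per-draw probability vector.

This is the one sampling machine behind both the personalized RF family and
the case-specific random forest: every tree is grown on n_train draws with
replacement, with draw probabilities that are uniform for a standard forest
and PSM-proportional for a case-specific one. Because the uniform case goes
through the same weighted-draw code path, a uniform-weight case-specific
forest is bit-identical to the standard forest under a shared seed.

Per-tree RNG streams are spawned from (seed, tree index), so tree t is
reproducible independently of how many trees are grown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

__all__ = ["BootstrapForest", "weighted_bootstrap"]


def weighted_bootstrap(weights: np.ndarray, n_draw: int,
                       rng: np.random.Generator | int) -> np.ndarray:
    """n_draw independent draws with replacement, P(draw j) = weights_j."""
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("weights must be a nonempty 1-D vector")
    if (w < 0).any() or not np.isclose(w.sum(), 1.0, atol=1e-8):
        raise ValueError("weights must be nonnegative and sum to 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return rng.choice(w.size, size=int(n_draw), replace=True, p=w / w.sum())


@dataclass
class BootstrapForest:
    """Classification forest over 0/1 labels; prediction = fraction of trees voting 1."""

    n_trees: int = 500
    mtry: int | None = None        # None -> floor(sqrt(p))
    nodesize: int = 1
    seed: int = 0
    _trees: list = field(default_factory=list, repr=False)

    def fit(self, X: np.ndarray, y: np.ndarray,
            weights: np.ndarray | None = None) -> "BootstrapForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n, p = X.shape
        w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, dtype=float)
        mtry = int(np.floor(np.sqrt(p))) if self.mtry is None else self.mtry
        mtry = min(max(mtry, 1), p)
        self._trees = []
        children = np.random.SeedSequence(self.seed).spawn(self.n_trees)
        for t in range(self.n_trees):
            rng = np.random.default_rng(children[t])
            idx = weighted_bootstrap(w, n, rng)
            ys = y[idx]
            if ys.min() == ys.max():
                self._trees.append(int(ys[0]))  # degenerate sample: constant vote
                continue
            tree = DecisionTreeClassifier(
                max_features=mtry,
                min_samples_leaf=self.nodesize,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], ys)
            self._trees.append(tree)
        return self

    def predict_risk(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees whose majority vote is death (class 1)."""
        if not self._trees:
            raise RuntimeError("forest is not fitted")
        X = np.asarray(X, dtype=float)
        votes = np.zeros(X.shape[0])
        for tree in self._trees:
            votes += tree if isinstance(tree, int) else tree.predict(X)
        return votes / len(self._trees)
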