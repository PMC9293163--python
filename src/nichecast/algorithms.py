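"""The six suitability learners used by the ensemble.

Each learner maps a matrix of climate values to a suitability score in [0, 1]
and is deterministic under its seed.  The families mirror the algorithms
conventionally bundled in SDM ensembles:

* ``GLM``     logistic regression with linear + quadratic terms
* ``GAM``     logistic regression on per-variable cubic spline bases
* ``ANN``     one-hidden-layer (5 unit) feed-forward classifier
* ``CTA``     single classification tree, depth-limited (default 8)
* ``RF``      500-tree random forest
* ``MAXENT``  L1-regularized logistic contrast of presences vs *background*
  points with linear + quadratic + pairwise-product features (the standard
  maximum-entropy / logistic equivalence for presence-background data)

All learners except MAXENT are trained on presences (1) vs pseudoabsences (0);
MAXENT contrasts presences with background.  Features are z-scored with
statistics from the training set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import PolynomialFeatures, SplineTransformer, StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = ["ALGORITHMS", "SuitabilityLearner", "make_learner"]

ALGORITHMS = ("GLM", "GAM", "ANN", "CTA", "MAXENT", "RF")


def _quadratic() -> PolynomialFeatures:
    return PolynomialFeatures(degree=2, interaction_only=False, include_bias=False)


def _build(algorithm: str, seed: int, config: dict) -> Pipeline:
    if algorithm == "GLM":
        steps = [("scale", StandardScaler()),
                 ("quad", _quadratic()),
                 ("clf", LogisticRegression(C=np.inf, max_iter=2000))]
    elif algorithm == "GAM":
        steps = [("scale", StandardScaler()),
                 ("spline", SplineTransformer(n_knots=config.get("gam_knots", 5),
                                              degree=3)),
                 ("clf", LogisticRegression(C=10.0, max_iter=2000))]
    elif algorithm == "ANN":
        steps = [("scale", StandardScaler()),
                 ("clf", MLPClassifier(hidden_layer_sizes=(config.get("ann_units", 5),),
                                       max_iter=config.get("ann_max_iter", 600),
                                       random_state=seed))]
    elif algorithm == "CTA":
        steps = [("clf", DecisionTreeClassifier(
            max_depth=config.get("cta_max_depth", 8),
            min_samples_leaf=config.get("cta_min_leaf", 5),
            random_state=seed))]
    elif algorithm == "RF":
        steps = [("clf", RandomForestClassifier(
            n_estimators=config.get("rf_trees", 500),
            min_samples_leaf=config.get("rf_min_leaf", 2),
            random_state=seed, n_jobs=1))]
    elif algorithm == "MAXENT":
        steps = [("scale", StandardScaler()),
                 ("quad", _quadratic()),
                 ("clf", LogisticRegression(l1_ratio=1.0, C=config.get("maxent_C", 1.0),
                                            solver="liblinear", max_iter=2000,
                                            random_state=seed))]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; "
                         f"expected one of {ALGORITHMS}")
    return Pipeline(steps)


@dataclass
class SuitabilityLearner:
    """A fitted member of the ensemble; `predict` returns values in [0, 1]."""

    algorithm: str
    seed: int
    config: dict = field(default_factory=dict)
    _pipeline: Pipeline | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SuitabilityLearner":
        y = np.asarray(y).astype(int)
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("need at least two points per class")
        pipe = _build(self.algorithm, self.seed, self.config)
        with warnings.catch_warnings():
            # incomplete MLP/IRLS convergence is scored by the AUC keep
            # filter, not surfaced as a warning per run
            warnings.simplefilter("ignore", ConvergenceWarning)
            pipe.fit(np.asarray(X, float), y)
        self._pipeline = pipe
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self._pipeline is None:
            raise RuntimeError("learner is not fitted")
        p = self._pipeline.predict_proba(np.asarray(X, float))[:, 1]
        return np.clip(p, 0.0, 1.0)


def make_learner(algorithm: str, seed: int,
                 config: dict | None = None) -> SuitabilityLearner:
    algorithm = algorithm.upper()
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return SuitabilityLearner(algorithm, seed, config or {})
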