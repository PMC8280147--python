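"""Reference classifiers and mutual-information feature ranking.

Four classifiers are exposed behind a common fit/predict_score contract:
logistic regression, linear discriminant analysis and random forest
delegate to scikit-learn (with effective hyperparameters recorded for the
run log), while Gaussian naive Bayes is implemented natively. Only the
random forest consumes a random state; it is fixed once per classifier
instance so that seed variation in the experiments comes exclusively from
the data splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .dataset import BINARY, LabeledDataset

CLASSIFIER_NAMES = ("logistic", "gnb", "lda", "random_forest")


class GaussianNaiveBayes:
    """Gaussian naive Bayes with per-feature class-conditional normals.

    Class priors are training frequencies; per-class variances get a small
    floor (1e-9 times the largest overall feature variance) so constant
    within-class features cannot divide by zero.
    """

    VAR_FLOOR_REL = 1e-9

    def fit(self, x: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=int)
        eps = self.VAR_FLOOR_REL * float(np.max(np.var(x, axis=0), initial=0.0))
        self.classes_ = np.array([0, 1])
        self.priors_ = np.array([np.mean(y == c) for c in self.classes_])
        if np.any(self.priors_ == 0):
            raise ValueError("both classes required to fit")
        self.means_ = np.vstack([x[y == c].mean(axis=0) for c in self.classes_])
        self.vars_ = np.vstack([x[y == c].var(axis=0) + eps for c in self.classes_])
        return self

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        log_joint = np.empty((x.shape[0], 2))
        for i, _ in enumerate(self.classes_):
            mu, var = self.means_[i], self.vars_[i]
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (x - mu) ** 2 / var, axis=1)
            log_joint[:, i] = np.log(self.priors_[i]) + ll
        shift = log_joint - log_joint.max(axis=1, keepdims=True)
        post = np.exp(shift)
        post /= post.sum(axis=1, keepdims=True)
        return post[:, 1]


@dataclass
class Classifier:
    """A named classifier satisfying the regimen contract.

    ``fit`` builds a fresh estimator every call (no state leaks between
    validation repetitions); ``predict_score`` returns class-1
    probabilities.
    """

    name: str
    internal_seed: int | None = None
    params: dict = field(default_factory=dict)
    _fitted: object = field(default=None, repr=False)

    def _new_estimator(self):
        if self.name == "logistic":
            return LogisticRegression(**self.params)
        if self.name == "lda":
            return LinearDiscriminantAnalysis(**self.params)
        if self.name == "random_forest":
            return RandomForestClassifier(random_state=self.internal_seed, **self.params)
        if self.name == "gnb":
            return GaussianNaiveBayes()
        raise ValueError(f"unknown classifier name {self.name!r}")

    def fit(self, x: np.ndarray, y: np.ndarray) -> "Classifier":
        est = self._new_estimator()
        est.fit(np.asarray(x, dtype=float), np.asarray(y, dtype=int))
        self._fitted = est
        return self

    def predict_score(self, x: np.ndarray) -> np.ndarray:
        if self._fitted is None:
            raise RuntimeError("classifier has not been fitted")
        if isinstance(self._fitted, GaussianNaiveBayes):
            scores = self._fitted.predict_score(np.asarray(x, dtype=float))
        else:
            scores = self._fitted.predict_proba(np.asarray(x, dtype=float))[:, 1]
        if not np.all(np.isfinite(scores)):
            raise RuntimeError("non-finite prediction scores")
        return scores

    def effective_config(self) -> dict:
        """Name, seed and full hyperparameters for the run log."""
        est = self._new_estimator()
        params = est.get_params() if hasattr(est, "get_params") else {"var_floor_rel": GaussianNaiveBayes.VAR_FLOOR_REL}
        return {
            "name": self.name,
            "internal_seed": self.internal_seed,
            "hyperparameters": {k: repr(v) for k, v in sorted(params.items())},
        }


def make_classifier(name: str, internal_seed: int | None = None, **params) -> Classifier:
    """Build one of the four reference classifiers by name.

    Only ``random_forest`` uses ``internal_seed``; the other three are
    deterministic. Logistic regression gets max_iter=1000 so the solver
    always converges deterministically on the cohort sizes used here.
    """
    if name not in CLASSIFIER_NAMES:
        raise ValueError(f"unknown classifier name {name!r}; known: {CLASSIFIER_NAMES}")
    if name == "logistic":
        params.setdefault("max_iter", 1000)
    return Classifier(name=name, internal_seed=internal_seed, params=params)


@dataclass(frozen=True)
class FeatureRanking:
    """Per-feature mutual information scores (nats) and the top-m selection."""

    scores: np.ndarray
    order: np.ndarray
    selected: np.ndarray


def _discrete_mi(codes: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in nats."""
    n = len(y)
    mi = 0.0
    for cx in np.unique(codes):
        px = np.mean(codes == cx)
        for cy in (0, 1):
            pxy = np.sum((codes == cx) & (y == cy)) / n
            if pxy > 0:
                py = np.mean(y == cy)
                mi += pxy * np.log(pxy / (px * py))
    return max(float(mi), 0.0)


def _equal_frequency_codes(values: np.ndarray, n_bins: int) -> np.ndarray:
    qs = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, values, side="right")


def mutual_information_rank(
    data: LabeledDataset, m: int, n_bins: int = 10
) -> FeatureRanking:
    """Rank features by plug-in mutual information with the label.

    Binary features use exact discrete MI; continuous features are first
    discretized into ``n_bins`` equal-frequency bins (making the score
    invariant to strictly monotone transforms and free of any random
    seed). Ties break by ascending feature index. A constant feature has
    MI 0.
    """
    if not 1 <= m <= data.p:
        raise ValueError("m must lie in [1, p]")
    if data.n_missing:
        raise ValueError("mutual information requires a complete feature matrix")
    scores = np.empty(data.p)
    for j in range(data.p):
        col = data.features[:, j]
        if data.feature_kinds[j] == BINARY:
            codes = col.astype(int)
        else:
            codes = _equal_frequency_codes(col, n_bins)
        scores[j] = _discrete_mi(codes, data.labels)
    order = np.lexsort((np.arange(data.p), -scores))
    return FeatureRanking(scores=scores, order=order, selected=order[:m].copy())
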