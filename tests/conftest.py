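import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from validstab.dataset import LabeledDataset
from validstab.synthetic_data import CohortSpec, calibrate_effect_scale, generate_cohort


class FixedLinearScorer:
    """Fit-free deterministic model: scores are a fixed function of the
    features, so every pooling-based regimen must agree with full-data
    scoring."""

    name = "fixed_linear"
    internal_seed = None

    def __init__(self, weights=None):
        self.weights = weights

    def fit(self, x, y):
        if self.weights is None:
            self.weights = np.ones(np.asarray(x).shape[1])
        return self

    def predict_score(self, x):
        return expit(np.asarray(x, dtype=float) @ self.weights)


class ConstantScorer:
    """Scores everything 0.5; AUC is 0.5 under midrank tie handling."""

    name = "constant"
    internal_seed = None

    def fit(self, x, y):
        return self

    def predict_score(self, x):
        return np.full(np.asarray(x).shape[0], 0.5)


@pytest.fixture
def fixed_scorer():
    return FixedLinearScorer()


@pytest.fixture
def constant_scorer():
    return ConstantScorer()


@pytest.fixture
def small_cohort():
    """200-patient cohort with signal, no missingness."""
    spec = CohortSpec(
        n_patients=200,
        prevalence=0.5,
        n_continuous=4,
        n_binary=2,
        effect_scale=1.0,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture
def tiny_dataset():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((40, 3))
    y = np.r_[np.ones(20, dtype=int), np.zeros(20, dtype=int)]
    return LabeledDataset(x, y)


@pytest.fixture(scope="session")
def primary_like_spec():
    """Cohort spec mirroring the primary study dataset, signal calibrated so
    the oracle latent score reaches AUC ~0.80."""
    spec = CohortSpec(
        n_patients=681,
        prevalence=0.54,
        n_continuous=20,
        n_binary=10,
        feature_correlation=0.2,
        seed=0,
    )
    scale = calibrate_effect_scale(spec, target_auc=0.80, tolerance=0.005)
    return dataclasses.replace(spec, effect_scale=scale)


@pytest.fixture(scope="session")
def primary_like_cohort(primary_like_spec):
    return generate_cohort(primary_like_spec)
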