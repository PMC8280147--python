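"""Synthetic clinical-style cohort generator.

Cohorts follow a linear-logit design: a block of equicorrelated standard
normal continuous features and independent Bernoulli(0.5) binary features,
a sparse alternating-sign coefficient pattern on a declared subset of the
columns, and labels drawn from the sigmoid of the latent score. The
intercept is solved numerically so the expected label prevalence matches
the requested one, and the overall signal strength can be calibrated so
the latent (oracle) score reaches a target AUC. Missingness, when
requested, is MCAR: each affected row receives exactly one missing cell in
a uniformly chosen continuous column.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import rankdata

from ._rng import derive_seed
from .dataset import BINARY, CONTINUOUS, LabeledDataset

#: Monte-Carlo sample size used when solving the intercept.
INTERCEPT_MC_N = 100_000
#: Tolerance on |expected prevalence - requested prevalence|.
INTERCEPT_TOL = 1e-3
#: Fixed stream index for internal (seed-independent by construction) draws.
_INTERNAL_STREAM = 0xC0C0


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a generated cohort.

    ``n_signal`` controls how many leading columns (continuous first, then
    binary) carry coefficients; the coefficient pattern is alternating-sign
    unit weights scaled by ``effect_scale``.
    """

    n_patients: int
    prevalence: float
    n_continuous: int = 20
    n_binary: int = 10
    feature_correlation: float = 0.0
    effect_scale: float = 1.0
    target_auc: float | None = None
    missing_fraction: float = 0.0
    n_signal: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n_continuous < 0 or self.n_binary < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_continuous + self.n_binary < 1:
            raise ValueError("at least one feature is required")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ValueError("feature_correlation must lie in [0, 1)")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be nonnegative")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.missing_fraction > 0 and self.n_continuous == 0:
            raise ValueError("missingness requires at least one continuous feature")
        if self.target_auc is not None and not 0.5 < self.target_auc < 1.0:
            raise ValueError("target_auc must lie in (0.5, 1)")
        if self.n_signal is not None and not 1 <= self.n_signal <= self.p:
            raise ValueError("n_signal must lie in [1, p]")

    @property
    def p(self) -> int:
        return self.n_continuous + self.n_binary

    @property
    def effective_n_signal(self) -> int:
        return self.n_signal if self.n_signal is not None else min(self.p, 10)


def coefficient_pattern(spec: CohortSpec) -> np.ndarray:
    """Unit-scale coefficient vector: alternating-sign weights on the first
    ``effective_n_signal`` columns, zeros elsewhere."""
    beta = np.zeros(spec.p)
    k = spec.effective_n_signal
    beta[:k] = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
    return beta


def _draw_design(spec: CohortSpec, n: int, rng: np.random.Generator):
    """Draw raw features and the centered design used for the logit."""
    rho = spec.feature_correlation
    nc, nb = spec.n_continuous, spec.n_binary
    if nc:
        eps = rng.standard_normal((n, nc))
        if rho > 0:
            shared = rng.standard_normal(n)
            x_cont = np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * eps
        else:
            x_cont = eps
    else:
        x_cont = np.empty((n, 0))
    if nb:
        x_bin = rng.integers(0, 2, size=(n, nb)).astype(float)
    else:
        x_bin = np.empty((n, 0))
    features = np.hstack([x_cont, x_bin])
    design = np.hstack([x_cont, x_bin - 0.5])  # binary columns centered
    return features, design


def _solve_intercept(spec: CohortSpec, effect_scale: float) -> float:
    """Root-find the intercept so E[sigmoid(b + s)] matches the prevalence.

    The expectation is Monte-Carlo over a fixed-seed internal sample, so the
    intercept depends only on the distributional parameters, not the cohort
    seed.
    """
    rng = np.random.default_rng(derive_seed(_INTERNAL_STREAM, spec.p))
    _, design = _draw_design(spec, INTERCEPT_MC_N, rng)
    latent = effect_scale * (design @ coefficient_pattern(spec))

    def gap(b: float) -> float:
        return float(np.mean(expit(b + latent))) - spec.prevalence

    intercept = brentq(gap, -40.0, 40.0, xtol=1e-10)
    if abs(gap(intercept)) > INTERCEPT_TOL:
        raise RuntimeError("intercept solve did not reach tolerance")
    return float(intercept)


def generate_cohort(spec: CohortSpec, return_latent: bool = False):
    """Generate a labeled cohort according to `spec`.

    Returns a :class:`LabeledDataset`; with ``return_latent=True`` also
    returns the latent (oracle) score vector, before any missingness is
    injected into the feature matrix.
    """
    rng = np.random.default_rng(spec.seed)
    features, design = _draw_design(spec, spec.n_patients, rng)
    intercept = _solve_intercept(spec, spec.effect_scale)
    latent = intercept + spec.effect_scale * (design @ coefficient_pattern(spec))
    labels = (rng.uniform(size=spec.n_patients) < expit(latent)).astype(int)

    if spec.missing_fraction > 0:
        n_rows = int(round(spec.missing_fraction * spec.n_patients))
        rows = rng.choice(spec.n_patients, size=n_rows, replace=False)
        cols = rng.integers(0, spec.n_continuous, size=n_rows)
        features[rows, cols] = np.nan

    names = [f"cont_{j}" for j in range(spec.n_continuous)] + [
        f"bin_{j}" for j in range(spec.n_binary)
    ]
    kinds = [CONTINUOUS] * spec.n_continuous + [BINARY] * spec.n_binary
    data = LabeledDataset(features, labels, names, kinds)
    return (data, latent) if return_latent else data


def _oracle_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    # midrank Mann-Whitney; local copy to keep calibration self-contained
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def calibrate_effect_scale(
    spec: CohortSpec,
    target_auc: float,
    tolerance: float = 0.005,
    mc_n: int = 50_000,
    max_iter: int = 60,
) -> float:
    """Bisection search for the effect scale whose latent-score AUC hits
    ``target_auc`` on a large Monte-Carlo sample.

    The oracle AUC is computed on the TRUE latent score against the
    generated labels — no model fitting is involved — and is monotone
    nondecreasing in the effect scale.
    """
    if not 0.5 < target_auc < 1.0:
        raise ValueError("target_auc must lie in (0.5, 1)")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if mc_n < 50_000:
        raise ValueError("mc_n must be at least 50000")

    rng = np.random.default_rng(derive_seed(spec.seed, _INTERNAL_STREAM + 1))
    _, design = _draw_design(spec, mc_n, rng)
    base = design @ coefficient_pattern(spec)
    u = rng.uniform(size=mc_n)

    def mc_auc(scale: float) -> float:
        b = _solve_intercept(spec, scale)
        latent = b + scale * base
        labels = (u < expit(latent)).astype(int)
        if labels.sum() in (0, len(labels)):
            raise RuntimeError("degenerate labels during calibration")
        return _oracle_auc(labels, latent)

    lo, hi = 0.0, 1.0
    it = 0
    while mc_auc(hi) < target_auc:
        lo, hi = hi, hi * 2.0
        it += 1
        if it > 20:
            raise RuntimeError("target AUC unreachable within iteration cap")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        a = mc_auc(mid)
        if abs(a - target_auc) <= tolerance:
            return mid
        if a < target_auc:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration did not converge within iteration cap")


def write_cohort_csv(data: LabeledDataset, spec: CohortSpec, path) -> None:
    """Write a cohort to CSV (empty field = missing) with a sidecar JSON
    recording the generating spec."""
    from .preprocessing import write_dataset

    path = Path(path)
    write_dataset(data, path)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    sidecar.write_text(json.dumps(asdict(spec), indent=2, sort_keys=True) + "\n")
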