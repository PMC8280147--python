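"""ROC-based inference.

Mann-Whitney AUC with midrank tie handling, ROC curves, the DeLong
structural-components variance estimator with Wald confidence intervals,
the Hanley-McNeil closed-form standard error, a non-directional z-test
between two independent ROC curves, and threshold-based secondary metrics
(accuracy, F1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata


@dataclass
class ScoredPredictions:
    """Paired (true label, predicted score) arrays.

    Scores from probabilistic models lie in [0, 1] but any real-valued
    ordering is accepted.
    """

    y_true: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.y_true = np.asarray(self.y_true)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.y_true.shape != self.scores.shape or self.y_true.ndim != 1:
            raise ValueError("y_true and scores must be equal-length 1-D arrays")
        if not np.all(np.isin(np.unique(self.y_true), [0, 1])):
            raise ValueError("y_true must contain only 0/1")
        self.y_true = self.y_true.astype(int)
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")

    @property
    def n1(self) -> int:
        return int(self.y_true.sum())

    @property
    def n0(self) -> int:
        return len(self.y_true) - self.n1

    def require_both_classes(self) -> None:
        if self.n1 == 0 or self.n0 == 0:
            raise ValueError("both classes must be present")


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix cell counts at a fixed decision threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def fpr(self) -> float:
        return self.fp / (self.tn + self.fp)

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)


@dataclass(frozen=True)
class AucEstimate:
    """AUC with DeLong variance and a Wald confidence interval."""

    auc: float
    variance: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    n1: int = 0
    n0: int = 0


@dataclass(frozen=True)
class RocComparison:
    """Unpaired two-sample comparison of two AUCs."""

    auc_a: float
    auc_b: float
    se_a: float
    se_b: float
    z: float
    p_two_sided: float
    method: str


def auc(preds: ScoredPredictions) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Equals the trapezoidal area under the empirical ROC curve.
    """
    preds.require_both_classes()
    ranks = rankdata(preds.scores)
    n1, n0 = preds.n1, preds.n0
    pos_rank_sum = ranks[preds.y_true == 1].sum()
    return float((pos_rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(preds: ScoredPredictions) -> np.ndarray:
    """Empirical ROC curve as an (k, 2) array of (FPR, TPR) points.

    Thresholds sweep the unique scores in descending order; the curve
    starts at (0, 0) and ends at (1, 1).
    """
    preds.require_both_classes()
    order = np.argsort(-preds.scores, kind="stable")
    y = preds.y_true[order]
    s = preds.scores[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last index of each tied-score block
    last = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    fpr = np.r_[0.0, fps[last] / preds.n0]
    tpr = np.r_[0.0, tps[last] / preds.n1]
    return np.column_stack([fpr, tpr])


def _structural_components(preds: ScoredPredictions):
    """Per-observation placement values V10 (positives) and V01 (negatives),
    using midranks (ties count 1/2)."""
    pos = preds.scores[preds.y_true == 1]
    neg = preds.scores[preds.y_true == 0]
    n1, n0 = len(pos), len(neg)
    r_all = rankdata(np.concatenate([pos, neg]))
    v10 = (r_all[:n1] - rankdata(pos)) / n0
    v01 = 1.0 - (r_all[n1:] - rankdata(neg)) / n1
    return v10, v01


def delong_variance(preds: ScoredPredictions) -> float:
    """DeLong variance of the AUC: S10/n1 + S01/n0 with S10, S01 the sample
    variances of the positive/negative structural components."""
    preds.require_both_classes()
    if preds.n1 < 2 or preds.n0 < 2:
        raise ValueError("DeLong variance needs at least 2 members per class")
    v10, v01 = _structural_components(preds)
    return float(np.var(v10, ddof=1) / preds.n1 + np.var(v01, ddof=1) / preds.n0)


def delong_ci(preds: ScoredPredictions, level: float = 0.95) -> AucEstimate:
    """Wald interval auc +/- z * sqrt(variance), clipped to [0, 1]."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = auc(preds)
    var = delong_variance(preds)
    half = norm.ppf(0.5 + level / 2) * np.sqrt(var)
    return AucEstimate(
        auc=a,
        variance=var,
        ci_low=float(max(0.0, a - half)),
        ci_high=float(min(1.0, a + half)),
        level=level,
        n1=preds.n1,
        n0=preds.n0,
    )


def hanley_mcneil_se(auc_value: float, n1: int, n0: int) -> float:
    """Closed-form AUC standard error with Q1 = A/(2-A), Q2 = 2A^2/(1+A)."""
    if not 0.0 <= auc_value <= 1.0:
        raise ValueError("auc_value must lie in [0, 1]")
    if n1 < 1 or n0 < 1:
        raise ValueError("class counts must be positive")
    a = auc_value
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    num = a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)
    return float(np.sqrt(max(num, 0.0) / (n1 * n0)))


def independent_roc_test(
    preds_a: ScoredPredictions,
    preds_b: ScoredPredictions,
    method: str = "hanley_mcneil",
) -> RocComparison:
    """Non-directional z-test between two independent ROC curves.

    z = (A_a - A_b) / sqrt(SE_a^2 + SE_b^2), with standard errors computed
    per `method` ("hanley_mcneil" or "delong").
    """
    auc_a, auc_b = auc(preds_a), auc(preds_b)
    if method == "hanley_mcneil":
        se_a = hanley_mcneil_se(auc_a, preds_a.n1, preds_a.n0)
        se_b = hanley_mcneil_se(auc_b, preds_b.n1, preds_b.n0)
    elif method == "delong":
        se_a = float(np.sqrt(delong_variance(preds_a)))
        se_b = float(np.sqrt(delong_variance(preds_b)))
    else:
        raise ValueError(f"unknown comparison method {method!r}")
    pooled = float(np.hypot(se_a, se_b))
    diff = auc_a - auc_b
    if pooled == 0.0:
        z = 0.0 if diff == 0.0 else float(np.sign(diff)) * np.inf
    else:
        z = diff / pooled
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if z == 0.0:
        p = 1.0
    return RocComparison(auc_a, auc_b, se_a, se_b, float(z), p, method)


def confusion_counts(preds: ScoredPredictions, threshold: float = 0.5) -> ConfusionCounts:
    """Cell counts when score >= threshold is called positive."""
    pred_pos = preds.scores >= threshold
    y = preds.y_true.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred_pos & y)),
        fp=int(np.sum(pred_pos & ~y)),
        tn=int(np.sum(~pred_pos & ~y)),
        fn=int(np.sum(~pred_pos & y)),
    )


def accuracy_f1(preds: ScoredPredictions, threshold: float = 0.5) -> tuple[float, float]:
    """(accuracy, F1) at the given threshold; F1 is 0 when no positives are
    predicted or present."""
    preds.require_both_classes()
    c = confusion_counts(preds, threshold)
    m = len(preds.y_true)
    accuracy = (c.tp + c.tn) / m
    denom = 2 * c.tp + c.fp + c.fn
    f1 = 2 * c.tp / denom if denom else 0.0
    return float(accuracy), float(f1)
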