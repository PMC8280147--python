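"""The validation regimens.

Each regimen takes a (dataset, classifier, seed) triple and returns pooled
out-of-sample predictions plus an AUC:

* ``split_validate`` — single stratified hold-out split (50/50 or 70/30).
* ``kfold_cv`` — stratified k-fold; predictions are pooled ("concatenated")
  across folds into two global arrays and a single global AUC is computed,
  rather than averaging per-fold AUCs.
* ``repeated_kfold`` — k-fold repeated with derived sub-seeds; pooled over
  all repeats * k folds.
* ``bootstrap_validate`` — train on n draws with replacement, evaluate on
  the out-of-bag instances; the headline AUC is the mean over replicates
  while the pooled concatenation is kept for CI computation.
* ``loo_validate`` — leave-one-out; seed-free.

Data partitions depend only on (regimen, seed) — never on the classifier —
so the same seed gives identical splits to every model.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .dataset import LabeledDataset
from .preprocessing import stratified_split
from .roc_stats import ScoredPredictions, auc

REGIMEN_TAGS = ("split5050", "split7030", "kfold10", "repeated10x10", "bootstrap500", "loo")


@runtime_checkable
class ClassifierContract(Protocol):
    """Anything with fit / predict_score / name can be validated."""

    name: str

    def fit(self, x: np.ndarray, y: np.ndarray): ...

    def predict_score(self, x: np.ndarray) -> np.ndarray: ...


@dataclass
class RegimenResult:
    """One seed's validation outcome for one classifier."""

    regimen: str
    seed: int | None
    pooled: ScoredPredictions
    auc_value: float
    auc_aggregation: str  # "pooled" or "mean_of_reps"
    per_rep_aucs: list[float] = field(default_factory=list)
    n_train: int | list[int] = 0
    n_test: int | list[int] = 0
    split_fingerprint: str = ""
    n_redraws: int = 0

    def to_json_dict(self) -> dict:
        return {
            "regimen": self.regimen,
            "seed": self.seed,
            "auc_value": self.auc_value,
            "auc_aggregation": self.auc_aggregation,
            "per_rep_aucs": list(self.per_rep_aucs),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "split_fingerprint": self.split_fingerprint,
            "n_redraws": self.n_redraws,
            "n_pooled": len(self.pooled.y_true),
        }

    def save(self, prefix) -> None:
        """Write metadata JSON plus the pooled predictions as CSV."""
        prefix = Path(prefix)
        prefix.with_suffix(".json").write_text(
            json.dumps(self.to_json_dict(), indent=2, sort_keys=True) + "\n"
        )
        pd.DataFrame({"y_true": self.pooled.y_true, "score": self.pooled.scores}).to_csv(
            prefix.with_suffix(".csv"), index=False
        )


def _fingerprint(index_groups) -> str:
    h = hashlib.sha256()
    for idx in index_groups:
        h.update(idx if isinstance(idx, bytes) else np.asarray(idx, dtype=np.int64).tobytes())
        h.update(b"|")
    return h.hexdigest()[:16]


def _fit_and_score(data, model, train_idx, test_idx):
    model.fit(data.features[train_idx], data.labels[train_idx])
    return model.predict_score(data.features[test_idx])


def split_validate(
    data: LabeledDataset, model: ClassifierContract, test_fraction: float, seed: int
) -> RegimenResult:
    """Single stratified hold-out split; AUC on the test-set predictions."""
    split = stratified_split(data.labels, test_fraction, seed)
    scores = _fit_and_score(data, model, split.train, split.test)
    pooled = ScoredPredictions(data.labels[split.test], scores)
    tag = "split5050" if abs(test_fraction - 0.5) < 1e-12 else "split7030"
    return RegimenResult(
        regimen=tag,
        seed=seed,
        pooled=pooled,
        auc_value=auc(pooled),
        auc_aggregation="pooled",
        n_train=len(split.train),
        n_test=len(split.test),
        split_fingerprint=_fingerprint([split.train, split.test]),
    )


def stratified_fold_assignment(labels, k: int, seed: int) -> list[np.ndarray]:
    """Partition row indices into k stratified folds.

    Within each class the members are shuffled by the seeded generator and
    dealt round-robin to the folds, so per-fold class counts differ by at
    most one.
    """
    labels = np.asarray(labels, dtype=int)
    if k < 2:
        raise ValueError("k must be at least 2")
    for cls in (0, 1):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} members")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        perm = rng.permutation(np.flatnonzero(labels == cls))
        for i, row in enumerate(perm):
            folds[i % k].append(int(row))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def kfold_cv(
    data: LabeledDataset, model: ClassifierContract, k: int = 10, seed: int = 0
) -> RegimenResult:
    """Stratified k-fold CV with predictions pooled across folds."""
    folds = stratified_fold_assignment(data.labels, k, seed)
    all_idx = np.arange(data.n)
    ys, ss, n_tr, n_te = [], [], [], []
    for test_idx in folds:
        train_idx = np.setdiff1d(all_idx, test_idx, assume_unique=True)
        ss.append(_fit_and_score(data, model, train_idx, test_idx))
        ys.append(data.labels[test_idx])
        n_tr.append(len(train_idx))
        n_te.append(len(test_idx))
    pooled = ScoredPredictions(np.concatenate(ys), np.concatenate(ss))
    return RegimenResult(
        regimen="kfold10",
        seed=seed,
        pooled=pooled,
        auc_value=auc(pooled),
        auc_aggregation="pooled",
        n_train=n_tr,
        n_test=n_te,
        split_fingerprint=_fingerprint(folds),
    )


def repeated_kfold(
    data: LabeledDataset,
    model: ClassifierContract,
    k: int = 10,
    repeats: int = 10,
    seed: int = 0,
) -> RegimenResult:
    """k-fold CV repeated with sub-seeds derived from `seed`; all repeats'
    fold predictions are pooled, so each sample appears `repeats` times."""
    if repeats < 1:
        raise ValueError("repeats must be positive")
    reps = [kfold_cv(data, model, k=k, seed=derive_seed(seed, r)) for r in range(repeats)]
    pooled = ScoredPredictions(
        np.concatenate([r.pooled.y_true for r in reps]),
        np.concatenate([r.pooled.scores for r in reps]),
    )
    return RegimenResult(
        regimen="repeated10x10",
        seed=seed,
        pooled=pooled,
        auc_value=auc(pooled),
        auc_aggregation="pooled",
        per_rep_aucs=[r.auc_value for r in reps],
        n_train=[n for r in reps for n in r.n_train],
        n_test=[n for r in reps for n in r.n_test],
        split_fingerprint=_fingerprint([bytes.fromhex(r.split_fingerprint) for r in reps]),
    )


def bootstrap_validate(
    data: LabeledDataset,
    model: ClassifierContract,
    n_reps: int = 500,
    seed: int = 0,
    max_redraws_per_rep: int = 100,
) -> RegimenResult:
    """Bootstrap out-of-bag validation.

    Each replicate trains on n instances drawn with replacement and scores
    every instance not drawn. The headline AUC is the mean of the per-
    replicate AUCs; the pooled concatenation over replicates is retained
    for confidence-interval computation. Replicates whose out-of-bag set
    lacks a class are redrawn (counted in ``n_redraws``).
    """
    n = data.n
    if n < 10:
        raise ValueError("bootstrap validation needs n >= 10")
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    all_idx = np.arange(n)
    ys, ss, rep_aucs, oob_sizes = [], [], [], []
    fingerprints = []
    n_redraws = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(derive_seed(seed, rep))
        for _ in range(max_redraws_per_rep):
            train_idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(all_idx, train_idx)
            if oob.size and len(np.unique(data.labels[oob])) == 2:
                break
            n_redraws += 1
        else:
            raise RuntimeError("could not draw a two-class out-of-bag set")
        scores = _fit_and_score(data, model, train_idx, oob)
        rep_pred = ScoredPredictions(data.labels[oob], scores)
        rep_aucs.append(auc(rep_pred))
        ys.append(rep_pred.y_true)
        ss.append(rep_pred.scores)
        oob_sizes.append(len(oob))
        fingerprints.append(train_idx)
    pooled = ScoredPredictions(np.concatenate(ys), np.concatenate(ss))
    return RegimenResult(
        regimen="bootstrap500",
        seed=seed,
        pooled=pooled,
        auc_value=float(np.mean(rep_aucs)),
        auc_aggregation="mean_of_reps",
        per_rep_aucs=rep_aucs,
        n_train=n,
        n_test=oob_sizes,
        split_fingerprint=_fingerprint(fingerprints),
        n_redraws=n_redraws,
    )


def loo_validate(data: LabeledDataset, model: ClassifierContract) -> RegimenResult:
    """Leave-one-out validation: n fits, each scoring its held-out sample.

    Seed-free — repeated invocations are identical.
    """
    n = data.n
    if n < 3:
        raise ValueError("leave-one-out needs n >= 3")
    if min(np.bincount(data.labels, minlength=2)) < 2:
        raise ValueError("each class needs at least 2 members")
    all_idx = np.arange(n)
    scores = np.empty(n)
    for i in range(n):
        train_idx = np.delete(all_idx, i)
        scores[i] = _fit_and_score(data, model, train_idx, np.array([i]))[0]
    pooled = ScoredPredictions(data.labels, scores)
    return RegimenResult(
        regimen="loo",
        seed=None,
        pooled=pooled,
        auc_value=auc(pooled),
        auc_aggregation="pooled",
        n_train=n - 1,
        n_test=[1] * n,
        split_fingerprint=_fingerprint([all_idx]),
    )


def run_regimen(
    data: LabeledDataset,
    model: ClassifierContract,
    regimen: str,
    seed: int,
    *,
    test_fraction: float | None = None,
    k: int = 10,
    repeats: int = 10,
    n_reps: int = 500,
) -> RegimenResult:
    """Dispatch a regimen by tag."""
    if regimen == "split5050":
        return split_validate(data, model, test_fraction or 0.5, seed)
    if regimen == "split7030":
        return split_validate(data, model, test_fraction or 0.3, seed)
    if regimen == "kfold10":
        return kfold_cv(data, model, k=k, seed=seed)
    if regimen == "repeated10x10":
        return repeated_kfold(data, model, k=k, repeats=repeats, seed=seed)
    if regimen == "bootstrap500":
        return bootstrap_validate(data, model, n_reps=n_reps, seed=seed)
    if regimen == "loo":
        return loo_validate(data, model)
    raise ValueError(f"unknown regimen {regimen!r}; known: {REGIMEN_TAGS}")
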