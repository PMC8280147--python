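"""CSV I/O, missing-data policies, and stratified index splitting.

Two missing-data policies are provided: complete-case row deletion and
mean column imputation. Imputation means are computed on the full dataset
by default (matching a preprocess-then-validate pipeline order); a
train-only variant is available through ``fit_rows``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import BINARY, CONTINUOUS, LabeledDataset


@dataclass(frozen=True)
class SplitIndices:
    """Disjoint train/test row-index lists covering the whole dataset."""

    train: np.ndarray
    test: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "train", np.asarray(self.train, dtype=int))
        object.__setattr__(self, "test", np.asarray(self.test, dtype=int))
        overlap = np.intersect1d(self.train, self.test)
        if overlap.size:
            raise ValueError("train and test indices overlap")


def _infer_kinds(frame: pd.DataFrame) -> list[str]:
    kinds = []
    for col in frame.columns:
        vals = frame[col].dropna().unique()
        kinds.append(BINARY if np.all(np.isin(vals, [0.0, 1.0])) else CONTINUOUS)
    return kinds


def read_dataset(path, label_column: str = "label") -> LabeledDataset:
    """Read a labeled dataset from CSV (header row, empty string = missing)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.empty:
        raise ValueError("empty dataset file")
    if label_column not in frame.columns:
        raise ValueError(f"label column {label_column!r} not found")
    labels = frame[label_column]
    if labels.isna().any():
        raise ValueError("missing values in the label column")
    if not np.all(np.isin(labels.unique(), [0, 1])):
        raise ValueError("labels must be binary 0/1")
    feats = frame.drop(columns=[label_column]).astype(float)
    return LabeledDataset(
        feats.to_numpy(),
        labels.to_numpy(dtype=int),
        list(feats.columns),
        _infer_kinds(feats),
    )


def write_dataset(data: LabeledDataset, path) -> None:
    """Write a dataset to CSV; missing cells become empty fields."""
    frame = pd.DataFrame(data.features, columns=data.feature_names)
    frame.insert(0, "label", data.labels)
    frame.to_csv(path, index=False)


def complete_case_filter(data: LabeledDataset) -> LabeledDataset:
    """Drop every row containing at least one missing cell (order preserved)."""
    keep = ~np.isnan(data.features).any(axis=1)
    if not keep.any():
        raise ValueError("complete-case filtering removed every row")
    kept_labels = data.labels[keep]
    if len(np.unique(kept_labels)) < 2:
        raise ValueError("complete-case filtering eliminated a class")
    return data.subset_rows(np.flatnonzero(keep))


def mean_impute(data: LabeledDataset, fit_rows=None) -> LabeledDataset:
    """Replace missing cells by the observed column mean.

    Means are computed over all rows by default, or over ``fit_rows`` only
    (e.g. a training split) when given.
    """
    feats = data.features.copy()
    ref = feats if fit_rows is None else feats[np.asarray(fit_rows, dtype=int)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns handled below
        col_means = np.nanmean(ref, axis=0)
    if np.isnan(col_means).any():
        raise ValueError("a column has no observed values to impute from")
    miss = np.isnan(feats)
    feats[miss] = np.broadcast_to(col_means, feats.shape)[miss]
    return LabeledDataset(feats, data.labels, list(data.feature_names), list(data.feature_kinds))


def stratified_split(labels, test_fraction: float, seed: int) -> SplitIndices:
    """Seeded stratified train/test partition.

    Within each class, round-half-up(test_fraction * class size) members go
    to the test side, chosen by a seeded uniform shuffle; the remainder
    trains. The same seed always yields the same split.
    """
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in (0, 1):
        members = np.flatnonzero(labels == cls)
        n_test = int(math.floor(test_fraction * len(members) + 0.5))
        if n_test == 0 or n_test == len(members):
            raise ValueError(f"class {cls} too small to appear on both sides")
        perm = rng.permutation(members)
        test_parts.append(perm[:n_test])
        train_parts.append(perm[n_test:])
    return SplitIndices(
        train=np.sort(np.concatenate(train_parts)),
        test=np.sort(np.concatenate(test_parts)),
    )
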