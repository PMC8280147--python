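"""Labeled tabular dataset container.

The universal input of the pipeline: an n x p feature matrix (floats, NaN
for missing cells), a binary outcome vector, and per-column metadata
distinguishing continuous from binary predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTINUOUS = "continuous"
BINARY = "binary"


@dataclass
class LabeledDataset:
    """Feature matrix plus binary labels and column metadata.

    Parameters
    ----------
    features : ndarray of shape (n, p)
        Float matrix; missing cells are ``nan``.
    labels : ndarray of shape (n,)
        Integer vector with values in {0, 1}.
    feature_names : list of str
        Length-p column names.
    feature_kinds : list of str
        Length-p tags, each ``"continuous"`` or ``"binary"``.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    feature_kinds: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or len(self.labels) != self.features.shape[0]:
            raise ValueError("labels length must equal the feature row count")
        uniq = np.unique(self.labels)
        if not np.all(np.isin(uniq, [0, 1])):
            raise ValueError("labels must contain only 0/1")
        if len(uniq) < 2:
            raise ValueError("both outcome classes must be present")
        self.labels = self.labels.astype(int)
        p = self.features.shape[1]
        if not self.feature_names:
            self.feature_names = [f"x{j}" for j in range(p)]
        if not self.feature_kinds:
            self.feature_kinds = [CONTINUOUS] * p
        if len(self.feature_names) != p or len(self.feature_kinds) != p:
            raise ValueError("column metadata length must equal feature count")
        bad = set(self.feature_kinds) - {CONTINUOUS, BINARY}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.features).sum())

    def subset_rows(self, idx) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        return LabeledDataset(
            self.features[idx],
            self.labels[idx],
            list(self.feature_names),
            list(self.feature_kinds),
        )

    def subset_features(self, cols) -> "LabeledDataset":
        cols = np.asarray(cols, dtype=int)
        return LabeledDataset(
            self.features[:, cols],
            self.labels,
            [self.feature_names[j] for j in cols],
            [self.feature_kinds[j] for j in cols],
        )

    def __eq__(self, other) -> bool:  # bit-level equality, NaN-aware
        if not isinstance(other, LabeledDataset):
            return NotImplemented
        return (
            self.features.shape == other.features.shape
            and np.array_equal(self.features, other.features, equal_nan=True)
            and np.array_equal(self.labels, other.labels)
            and self.feature_names == other.feature_names
            and self.feature_kinds == other.feature_kinds
        )
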