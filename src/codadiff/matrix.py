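"""Core containers: integer count matrices and sample-to-group assignments.

A sequencing count matrix is compositional: each column (sample) carries
only relative information because total depth is an artifact of the
instrument. Everything downstream (Dirichlet resampling, log-ratio
transformation) treats columns as closed compositions; this module only
stores and validates the raw integer counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GroupAssignment",
    "InputError",
    "ParameterError",
    "ReferenceSelectionError",
]


class InputError(ValueError):
    """Invalid input data (counts, labels, call tables)."""


class ParameterError(ValueError):
    """Invalid run-time parameter (prior, instance count, threshold)."""


class ReferenceSelectionError(ValueError):
    """A denominator reference set could not be built."""


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise InputError(f"duplicate {what} ID: {i!r}")
        seen.add(i)
    return ids


@dataclass
class CountMatrix:
    """Feature-by-sample matrix of non-negative integer counts.

    Parameters
    ----------
    values
        Array of shape ``(n_features, n_samples)``; every entry must be a
        non-negative integer (integral floats are accepted and cast).
    feature_ids, sample_ids
        Unique row / column identifiers.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise InputError(f"counts must be 2-D, got shape {values.shape}")
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.issubdtype(values.dtype, np.number):
                raise InputError("counts must be numeric")
            frac = values != np.floor(values)
            if frac.any():
                i, j = np.argwhere(frac)[0]
                raise InputError(
                    f"non-integer count {values[i, j]!r} at feature index {i},"
                    f" sample index {j}"
                )
        values = values.astype(np.int64, copy=False)
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise InputError(
                f"negative count {values[i, j]} at feature index {i}, sample index {j}"
            )
        self.values = values
        self.feature_ids = _check_unique(self.feature_ids, "feature")
        self.sample_ids = _check_unique(self.sample_ids, "sample")
        if len(self.feature_ids) != values.shape[0]:
            raise InputError("feature_ids length does not match row count")
        if len(self.sample_ids) != values.shape[1]:
            raise InputError("sample_ids length does not match column count")
        if values.shape[1] < 2:
            raise InputError("a count matrix needs at least 2 samples")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def feature_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Map feature IDs to integer row indices; unknown IDs raise."""
        lookup = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in feature_ids if f not in lookup]
        if missing:
            raise InputError(f"unknown feature IDs: {missing[:5]}")
        return np.asarray([lookup[f] for f in feature_ids], dtype=np.intp)

    def subset(self, rows: np.ndarray | None = None, cols: np.ndarray | None = None) -> "CountMatrix":
        rows = np.arange(self.n_features) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_samples) if cols is None else np.asarray(cols)
        return CountMatrix(
            self.values[np.ix_(rows, cols)],
            [self.feature_ids[i] for i in rows],
            [self.sample_ids[j] for j in cols],
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        return cls(frame.to_numpy(), list(frame.index.astype(str)), list(frame.columns.astype(str)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class GroupAssignment:
    """Sample-to-group labels for a two-group comparison."""

    labels: Mapping[str, str] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Sequence[tuple[str, str]]) -> "GroupAssignment":
        return cls({str(s): str(g) for s, g in pairs})

    def group_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.labels.values())))

    def split(self, counts: CountMatrix) -> tuple[tuple[str, str], np.ndarray, np.ndarray]:
        """Column indices of the two groups, in sorted label order.

        Every sample in ``counts`` must be labelled, exactly two distinct
        labels must be present, and each group needs at least 2 samples.
        """
        missing = [s for s in counts.sample_ids if s not in self.labels]
        if missing:
            raise InputError(f"samples without a group label: {missing[:5]}")
        names = sorted({self.labels[s] for s in counts.sample_ids})
        if len(names) != 2:
            raise InputError(f"exactly 2 groups required, found {len(names)}: {names}")
        idx = {
            g: np.asarray(
                [j for j, s in enumerate(counts.sample_ids) if self.labels[s] == g],
                dtype=np.intp,
            )
            for g in names
        }
        for g in names:
            if idx[g].size < 2:
                raise InputError(f"group {g!r} has fewer than 2 samples")
        return (names[0], names[1]), idx[names[0]], idx[names[1]]
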