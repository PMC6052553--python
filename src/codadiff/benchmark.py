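"""Scoring DE calls against simulated truth: precision, recall, empirical FDR.

Performance is read off a 2x2 contingency of the simulated DE state against
the predicted state. A run that calls nothing has *undefined* precision
(0/0), which is recorded as missing rather than zero — a method that stays
silent is not a method that is always wrong. Empirical FDR is 1 - precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import CountMatrix, InputError
from .simulate import SimTruth

__all__ = ["Confusion", "BenchmarkSummary", "filter_low_counts", "score", "aggregate"]


def filter_low_counts(
    counts: CountMatrix, min_count: int = 10, min_samples: int = 20
) -> CountMatrix:
    """Keep features with at least ``min_count`` counts in at least
    ``min_samples`` samples (both comparisons inclusive).

    May return a matrix with zero features; callers must handle that.
    """
    if min_count < 0 or min_samples < 0:
        raise InputError("filter thresholds must be >= 0")
    keep = (counts.values >= min_count).sum(axis=1) >= min_samples
    return counts.subset(np.flatnonzero(keep))


@dataclass
class Confusion:
    """2x2 tally of predicted vs simulated DE state."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def precision(self) -> float | None:
        called = self.tp + self.fp
        return self.tp / called if called else None

    @property
    def recall(self) -> float | None:
        positives = self.tp + self.fn
        return self.tp / positives if positives else None

    @property
    def fdr(self) -> float | None:
        p = self.precision
        return None if p is None else 1.0 - p


def score(calls: Sequence[bool], truth: SimTruth | Sequence[bool]) -> Confusion:
    """Tally calls against truth (feature order must match)."""
    calls = np.asarray(calls, dtype=bool)
    is_de = truth.is_de if isinstance(truth, SimTruth) else np.asarray(truth, dtype=bool)
    if calls.shape != is_de.shape:
        raise InputError(
            f"calls ({calls.shape}) and truth ({is_de.shape}) lengths differ"
        )
    return Confusion(
        tp=int(np.sum(calls & is_de)),
        fp=int(np.sum(calls & ~is_de)),
        tn=int(np.sum(~calls & ~is_de)),
        fn=int(np.sum(~calls & is_de)),
    )


@dataclass
class BenchmarkSummary:
    """Per-run metrics plus grouped means/sds across repeats.

    ``runs`` has one row per (Confusion, metadata) record; undefined
    precision/FDR appear as NaN. ``summary`` groups by whichever of
    ``method``, ``transform``, ``n_per_group`` the metadata carries and
    reports means, sds and the number of runs with no calls (missing
    precision) — those runs are excluded from the precision/FDR means.
    """

    runs: pd.DataFrame
    summary: pd.DataFrame


_GROUP_KEYS = ("method", "transform", "n_per_group")


def aggregate(records: Sequence[tuple[Confusion, Mapping]]) -> BenchmarkSummary:
    """Tabulate and summarise a batch of scored runs."""
    if not records:
        raise InputError("no records to aggregate")
    rows = []
    for conf, meta in records:
        row = dict(meta)
        row.update(
            TP=conf.tp, FP=conf.fp, TN=conf.tn, FN=conf.fn,
            precision=np.nan if conf.precision is None else conf.precision,
            recall=np.nan if conf.recall is None else conf.recall,
            fdr=np.nan if conf.fdr is None else conf.fdr,
        )
        rows.append(row)
    runs = pd.DataFrame(rows)

    keys = [k for k in _GROUP_KEYS if k in runs.columns]
    grouped = runs.groupby(keys, dropna=False) if keys else runs.groupby(lambda _: "all")
    summary = grouped.agg(
        n_runs=("TP", "size"),
        n_no_calls=("precision", lambda s: int(s.isna().sum())),
        precision_mean=("precision", "mean"),
        precision_sd=("precision", "std"),
        recall_mean=("recall", "mean"),
        recall_sd=("recall", "std"),
        fdr_mean=("fdr", "mean"),
        fdr_sd=("fdr", "std"),
    ).reset_index()
    return BenchmarkSummary(runs, summary)
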