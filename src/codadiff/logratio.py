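"""Denominator-reference log-ratio transformations.

All transformations here share one form: each component of a sample's
composition is divided by the geometric mean of a *reference* subset of
components, then logged,

    lr(x)_i = ln( x_i / g(x[ref]) ),

differing only in how the reference is chosen:

``clr``
    reference = all features (the centered log-ratio).
``iqlr``
    reference = features whose variability lies within the inter-quartile
    range, a robustification against asymmetric up/down regulation.
``malr``
    reference = a user-declared set of equally-expressed features (the
    best-case normalisation when a ground-truth reference is known).
``iilr`` (``ii1`` / ``ii5``)
    iterative iqlr: the reference is refined by re-running the full
    differential-expression procedure and keeping the features it did NOT
    call, once (ii1) or five times (ii5).

Because every sample vector is divided by a single scalar before the log,
the result is invariant to multiplying a sample by any positive constant —
the compositional perturbation invariance that replaces library-size
normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import numpy as np

from .matrix import CountMatrix, GroupAssignment, ReferenceSelectionError
from .mc import DEFAULT_PRIOR, MonteCarloSet, point_estimate

__all__ = [
    "ReferenceSet",
    "TransformedSet",
    "geometric_mean",
    "transform",
    "transform_instances",
    "select_iqlr_reference",
    "iqr_window",
    "iterative_reference",
]


@dataclass
class ReferenceSet:
    """Feature indices whose geometric mean is the transform denominator."""

    indices: np.ndarray
    kind: str  # "all" | "iqr" | "user" | "iterative"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.size == 0:
            raise ReferenceSelectionError("reference set is empty")


@dataclass
class TransformedSet:
    """Log-ratio values for every Monte Carlo instance, ``(K, D, S)``."""

    values: np.ndarray
    reference: ReferenceSet
    transform_name: str


def geometric_mean(x: np.ndarray) -> float:
    """Geometric mean ``exp(mean(ln x))`` of a strictly positive vector."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("geometric mean requires a non-empty, strictly positive vector")
    return float(np.exp(np.mean(np.log(x))))


def transform(x: np.ndarray, ref: ReferenceSet) -> np.ndarray:
    """Log-ratio transform one sample vector against a reference set."""
    x = np.asarray(x, dtype=np.float64)
    if np.any(x <= 0):
        raise ValueError("sample vector must be strictly positive")
    logx = np.log(x)
    return logx - logx[ref.indices].mean()


def transform_instances(mcs: MonteCarloSet, ref: ReferenceSet, name: str) -> TransformedSet:
    """Apply the reference log-ratio to every instance and sample at once."""
    logp = np.log(mcs.proportions)
    denom = logp[:, ref.indices, :].mean(axis=1, keepdims=True)
    return TransformedSet(logp - denom, ref, name)


def all_features_reference(counts: CountMatrix) -> ReferenceSet:
    return ReferenceSet(np.arange(counts.n_features), "all")


def iqr_window(scores: np.ndarray) -> np.ndarray:
    """Indices whose score lies within [Q1, Q3] of the score distribution.

    Quartiles use linear interpolation; both bounds are inclusive, so a
    fully tied score vector returns every index.
    """
    scores = np.asarray(scores, dtype=np.float64)
    q1, q3 = np.quantile(scores, [0.25, 0.75])
    return np.flatnonzero((scores >= q1) & (scores <= q3))


def select_iqlr_reference(
    counts: CountMatrix,
    prior: float = DEFAULT_PRIOR,
    strategy: str = "clr",
) -> ReferenceSet:
    """Features with inter-quartile-range variability, for the iqlr denominator.

    What "variability" means is a modelling choice, so the score is
    pluggable:

    ``"clr"`` (default)
        per-feature variance, across samples, of clr-transformed
        posterior-mean proportions — scale-free, so sequencing depth does
        not masquerade as variability;
    ``"log"``
        variance of ``log(count + prior)``;
    ``"raw"``
        variance of the raw counts.

    Scoring the deterministic posterior means (rather than individual Monte
    Carlo draws) keeps the reference fixed for all instances of a run and
    invariant to sample relabelling.
    """
    if counts.n_features < 4:
        raise ReferenceSelectionError("iqlr selection needs at least 4 features")
    if strategy == "clr":
        logp = np.log(point_estimate(counts, prior))
        scored = logp - logp.mean(axis=0, keepdims=True)
    elif strategy == "log":
        scored = np.log(counts.values + prior)
    elif strategy == "raw":
        scored = counts.values.astype(np.float64)
    else:
        raise ValueError(f"unknown iqlr variability strategy {strategy!r}")
    scores = scored.var(axis=1, ddof=1)
    return ReferenceSet(iqr_window(scores), "iqr")


def iterative_reference(
    counts: CountMatrix,
    groups: GroupAssignment,
    n_iter: int = 1,
    *,
    n_instances: int = 128,
    prior: float = DEFAULT_PRIOR,
    seed: int = 0,
    threshold: float = 0.05,
) -> ReferenceSet:
    """Refine the denominator by re-running the DE procedure.

    Iteration 0 runs the full pipeline with the iqlr reference; each
    subsequent reference is the set of features the previous run did *not*
    call differentially expressed (expected BH rank-sum p >= ``threshold``),
    which should approach the ideal equally-expressed reference. If an
    iteration would leave fewer than ``max(10, 0.1 * n_features)`` features
    (a pathological shrinkage, e.g. everything called DE), the reference
    falls back to iqlr with a warning and iteration stops.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    from .detest import expected_de  # deferred: detest imports this module

    iqlr_ref = select_iqlr_reference(counts, prior)
    ref = iqlr_ref
    D = counts.n_features
    floor = min(max(10, ceil(0.1 * D)), D)
    for i in range(n_iter):
        sub_seed = int(np.random.SeedSequence(seed, spawn_key=(i,)).generate_state(1)[0])
        result = expected_de(
            counts, groups, ref, name="iqlr" if i == 0 else "iterative",
            n_instances=n_instances, prior=prior, seed=sub_seed, threshold=threshold,
        )
        keep = np.flatnonzero(result.wi_eBH >= threshold)
        if keep.size < floor:
            warnings.warn(
                f"iteration {i}: only {keep.size} features left undeclared; "
                "falling back to the iqlr reference",
                RuntimeWarning,
                stacklevel=2,
            )
            return ReferenceSet(iqlr_ref.indices.copy(), "iterative")
        ref = ReferenceSet(keep, "iterative")
    return ref
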