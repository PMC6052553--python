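"""Per-instance univariate testing and expected (averaged) BH p-values.

For each Monte Carlo instance the log-ratio values are compared between the
two groups feature-by-feature with the Wilcoxon rank-sum test and Welch's
t-test; each instance's p-vector is Benjamini-Hochberg adjusted *within the
instance*, and the per-feature expectation (arithmetic mean across the K
instances) of the adjusted values yields the ``wi.eBH`` / ``we.eBH``
columns. A feature is called differentially expressed when its expected
adjusted p-value falls below the significance threshold (0.05 by default).

Averaging adjusted p-values across posterior draws is deliberately
conservative: a feature must be significant consistently, not just in a
lucky draw. A corollary worth knowing: with 2 or 3 replicates per group the
smallest attainable two-sided rank-sum p-value is 1/3 or 0.1 respectively,
so the rank-sum caller can never reach 0.05 — no calls, by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import CountMatrix, GroupAssignment, InputError, ParameterError
from .mc import DEFAULT_PRIOR, sample_instances
from .logratio import (
    ReferenceSet,
    all_features_reference,
    iterative_reference,
    select_iqlr_reference,
    transform_instances,
)

__all__ = ["DEResult", "wilcoxon_p", "welch_p", "bh_adjust", "run_de", "TRANSFORMS"]

TRANSFORMS = ("clr", "iqlr", "malr", "ii1", "ii5")

# Largest combined sample size for which the ties-free rank-sum null is
# enumerated exactly; beyond it the tie-corrected normal approximation is used.
EXACT_LIMIT = 30


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values, row-wise, for (D, n1) vs (D, n2) arrays."""
    n = a.shape[1] + b.shape[1]
    p = np.empty(a.shape[0], dtype=np.float64)
    if n <= EXACT_LIMIT:
        pooled = np.sort(np.concatenate([a, b], axis=1), axis=1)
        tied = (np.diff(pooled, axis=1) == 0).any(axis=1)
        free = ~tied
        if free.any():
            p[free] = np.atleast_1d(
                stats.mannwhitneyu(a[free], b[free], axis=1, method="exact").pvalue
            )
        if tied.any():  # exact path refuses ties
            p[tied] = np.atleast_1d(
                stats.mannwhitneyu(a[tied], b[tied], axis=1, method="asymptotic").pvalue
            )
    else:
        p[:] = np.atleast_1d(stats.mannwhitneyu(a, b, axis=1, method="asymptotic").pvalue)
    return np.clip(p, 0.0, 1.0)


def _welch_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided Welch t-test p-values, row-wise, degenerate rows patched.

    Rows where both groups are constant get p = 1 when the constants agree
    and the smallest positive float when they differ (an infinite-t limit).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.atleast_1d(stats.ttest_ind(a, b, axis=1, equal_var=False).pvalue)
    degenerate = np.isnan(p)
    if degenerate.any():
        same = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p[degenerate & same] = 1.0
        p[degenerate & ~same] = np.finfo(np.float64).tiny
    return np.clip(p, 0.0, 1.0)


def wilcoxon_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when the combined sample size is at most 30 and the
    data are ties-free; otherwise a tie-corrected normal approximation with
    continuity correction.
    """
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    return float(_rank_sum_p(a[None, :], b[None, :])[0])


def welch_p(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Welch t-test p-value (Welch-Satterthwaite df)."""
    a, b = np.asarray(a, dtype=np.float64), np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 observations")
    return float(_welch_p(a[None, :], b[None, :])[0])


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or p.min() < 0 or p.max() > 1:
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResult:
    """Per-feature expected p-values, effect sizes and DE calls."""

    feature_ids: list[str]
    wi_ep: np.ndarray
    wi_eBH: np.ndarray
    we_ep: np.ndarray
    we_eBH: np.ndarray
    effect_median_diff: np.ndarray
    called: np.ndarray
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with the conventional wi.eBH / we.eBH column names."""
        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "wi.ep": self.wi_ep,
                "wi.eBH": self.wi_eBH,
                "we.ep": self.we_ep,
                "we.eBH": self.we_eBH,
                "effect.median.diff": self.effect_median_diff,
                "called": self.called,
            }
        )


def expected_de(
    counts: CountMatrix,
    groups: GroupAssignment,
    reference: ReferenceSet,
    *,
    name: str,
    n_instances: int,
    prior: float,
    seed: int,
    threshold: float,
    call_column: str = "wi.eBH",
) -> DEResult:
    """Run the Monte-Carlo test engine with a fixed denominator reference."""
    (g1, g2), idx1, idx2 = groups.split(counts)
    mcs = sample_instances(counts, n_instances, prior, seed)
    T = transform_instances(mcs, reference, name).values
    K = T.shape[0]
    wi_p = np.empty((K, counts.n_features))
    we_p = np.empty_like(wi_p)
    wi_q = np.empty_like(wi_p)
    we_q = np.empty_like(wi_p)
    eff = np.empty_like(wi_p)
    for k in range(K):
        a, b = T[k][:, idx1], T[k][:, idx2]
        wi_p[k] = _rank_sum_p(a, b)
        we_p[k] = _welch_p(a, b)
        wi_q[k] = bh_adjust(wi_p[k])
        we_q[k] = bh_adjust(we_p[k])
        eff[k] = np.median(b, axis=1) - np.median(a, axis=1)
    wi_eBH = wi_q.mean(axis=0)
    we_eBH = we_q.mean(axis=0)
    called = (wi_eBH if call_column == "wi.eBH" else we_eBH) < threshold
    return DEResult(
        feature_ids=list(counts.feature_ids),
        wi_ep=wi_p.mean(axis=0),
        wi_eBH=wi_eBH,
        we_ep=we_p.mean(axis=0),
        we_eBH=we_eBH,
        effect_median_diff=np.median(eff, axis=0),
        called=called,
        metadata={
            "transform": name,
            "n_instances": int(n_instances),
            "prior": float(prior),
            "seed": int(seed),
            "threshold": float(threshold),
            "call_column": call_column,
            "group_1": g1,
            "group_2": g2,
            "n_reference": int(reference.indices.size),
        },
    )


def run_de(
    counts: CountMatrix,
    groups: GroupAssignment,
    transform_name: str = "clr",
    n_instances: int = 128,
    prior: float = DEFAULT_PRIOR,
    seed: int = 0,
    threshold: float = 0.05,
    reference_features: Sequence[str] | None = None,
    call_column: str = "wi.eBH",
) -> DEResult:
    """Full differential-expression procedure on a two-group count matrix.

    Parameters
    ----------
    transform_name
        One of ``clr``, ``iqlr``, ``malr`` (requires ``reference_features``),
        ``ii1`` or ``ii5`` (iterative iqlr with 1 or 5 refinements).
    n_instances
        Monte Carlo instances K; 128 by default, 8 for a fast profile.
    reference_features
        Feature IDs forming the malr denominator; unknown IDs are an error.
    call_column
        Which expected adjusted p-value drives the ``called`` flag,
        ``"wi.eBH"`` (rank-sum, default) or ``"we.eBH"`` (Welch).

    Effect sizes are reported on the transformed (natural-log-ratio) scale
    as the median across instances of the between-group difference of
    medians (group 2 minus group 1, groups in sorted label order).
    """
    if transform_name not in TRANSFORMS:
        raise ParameterError(f"unknown transform {transform_name!r}; choose from {TRANSFORMS}")
    if not (0.0 < threshold < 1.0):
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    if call_column not in ("wi.eBH", "we.eBH"):
        raise ParameterError(f"call_column must be wi.eBH or we.eBH, got {call_column!r}")
    groups.split(counts)  # validate the design before any sampling

    if transform_name == "clr":
        ref = all_features_reference(counts)
    elif transform_name == "iqlr":
        ref = select_iqlr_reference(counts, prior)
    elif transform_name == "malr":
        if reference_features is None:
            raise ParameterError("malr requires a reference feature list")
        ref = ReferenceSet(counts.feature_index(reference_features), "user")
    else:
        n_iter = 1 if transform_name == "ii1" else 5
        ref = iterative_reference(
            counts, groups, n_iter,
            n_instances=n_instances, prior=prior, seed=seed, threshold=threshold,
        )
    return expected_de(
        counts, groups, ref,
        name=transform_name, n_instances=n_instances, prior=prior,
        seed=seed, threshold=threshold, call_column=call_column,
    )
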