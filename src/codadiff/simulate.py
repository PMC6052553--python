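"""Negative-binomial count simulator with known differential-expression truth.

The generator emulates a two-group RNA-Seq benchmark at the count level:
features receive a fold-change category by weighted lottery (a 70/30 split
of equally-expressed vs differentially-expressed features, with 4x, 2x and
1.5x changes up and down), baseline means are drawn from a long-tailed
log-normal, each sample's expected depth is scaled by a library-size weight
whose mean differs between groups by 0.20 (within-group sd 0.05), and counts
are drawn from a negative binomial with variance ``m + m^2 / r``.

Two dispersion regimes are provided: ``low`` uses ``r = mu / 3`` (variance
roughly 4x the mean — near-technical noise), ``high`` uses ``r = 1`` so the
variance equals the mean plus the mean squared — extremely variable data on
which any method's recall is poor.

Populations of 80 samples per group are sub-sampled without replacement into
repeat datasets of 2, 3, 5, 10 or 20 replicates per group (20 repeats by
convention) to map performance against sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .matrix import CountMatrix, GroupAssignment, InputError

__all__ = [
    "CATEGORY_FOLD",
    "DEFAULT_WEIGHTS",
    "SimDesign",
    "SimTruth",
    "SimOutput",
    "assign_truth",
    "draw_library_weights",
    "simulate_counts",
    "simulate",
    "subsample",
]

#: Fold-change multiplier applied to the group-2 mean, per category.
CATEGORY_FOLD: dict[str, float] = {
    "4x-up": 4.0,
    "2x-up": 2.0,
    "1.5x-up": 1.5,
    "equal": 1.0,
    "1.5x-down": 1.0 / 1.5,
    "2x-down": 0.5,
    "4x-down": 0.25,
}

DEFAULT_WEIGHTS: dict[str, float] = {
    "4x-up": 0.03,
    "2x-up": 0.07,
    "1.5x-up": 0.09,
    "1.5x-down": 0.06,
    "2x-down": 0.03,
    "4x-down": 0.02,
    "equal": 0.70,
}


class ConfigError(ValueError):
    """Invalid simulation design."""


@dataclass
class SimDesign:
    """Benchmark design parameters.

    Attributes
    ----------
    n_features, n_per_group
        Feature count and per-group population size.
    weights
        Fold-change category probabilities; must sum to 1.
    dispersion
        ``"low"`` (r = mu / size_low_factor) or ``"high"`` (r = 1).
    size_low_factor
        Denominator of the low-dispersion size, default 3 (r = mu/3).
    lib_weight_means, lib_weight_sd, lib_weight_floor
        Per-group means (1.0 and 1.2 — a 0.20 between-group difference),
        within-group sd (0.05) and positivity floor of the multiplicative
        library-size weights.
    baseline_log_mean, baseline_log_sd, baseline_min
        Log-normal parameters of the per-feature baseline mean, clamped
        below at ``baseline_min``.
    """

    n_features: int = 10_000
    n_per_group: int = 80
    weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    dispersion: str = "low"
    size_low_factor: float = 3.0
    lib_weight_means: tuple[float, float] = (1.0, 1.2)
    lib_weight_sd: float = 0.05
    lib_weight_floor: float = 0.01
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    baseline_min: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(CATEGORY_FOLD)
        if unknown:
            raise ConfigError(f"unknown fold-change categories: {sorted(unknown)}")
        w = np.asarray(list(self.weights.values()), dtype=np.float64)
        if w.size == 0 or (w < 0).any():
            raise ConfigError("category weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"category weights must sum to 1, got {w.sum():.6f}")
        if self.dispersion not in ("low", "high"):
            raise ConfigError(f"dispersion must be 'low' or 'high', got {self.dispersion!r}")
        if self.n_features < 2 or self.n_per_group < 2:
            raise ConfigError("need at least 2 features and 2 samples per group")
        if self.lib_weight_sd < 0 or self.lib_weight_floor <= 0:
            raise ConfigError("library-weight sd must be >= 0 and floor > 0")
        if self.size_low_factor <= 0 or self.baseline_min <= 0 or self.baseline_log_sd < 0:
            raise ConfigError("baseline and size parameters must be positive")

    def to_dict(self) -> dict:
        return {
            "n_features": self.n_features,
            "n_per_group": self.n_per_group,
            "weights": dict(self.weights),
            "dispersion": self.dispersion,
            "size_low_factor": self.size_low_factor,
            "lib_weight_means": list(self.lib_weight_means),
            "lib_weight_sd": self.lib_weight_sd,
            "lib_weight_floor": self.lib_weight_floor,
            "baseline_log_mean": self.baseline_log_mean,
            "baseline_log_sd": self.baseline_log_sd,
            "baseline_min": self.baseline_min,
        }


@dataclass
class SimTruth:
    """Gold standard: per-feature category, fold change and DE state."""

    feature_ids: list[str]
    category: np.ndarray
    fold_change: np.ndarray
    is_de: np.ndarray

    def subset(self, rows: np.ndarray) -> "SimTruth":
        rows = np.asarray(rows)
        return SimTruth(
            [self.feature_ids[i] for i in rows],
            self.category[rows],
            self.fold_change[rows],
            self.is_de[rows],
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": self.feature_ids,
                "category": self.category,
                "fold_change": self.fold_change,
                "is_de": self.is_de,
            }
        )


@dataclass
class SimOutput:
    """A simulated dataset: counts, gold standard, weights and design echo."""

    counts: CountMatrix
    truth: SimTruth
    groups: GroupAssignment
    library_weights: np.ndarray
    design: SimDesign


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def assign_truth(design: SimDesign, seed: int = 0) -> SimTruth:
    """Assign each feature a fold-change category by weighted lottery."""
    cats = np.asarray(list(design.weights.keys()))
    probs = np.asarray(list(design.weights.values()), dtype=np.float64)
    rng = _rng(seed, 1)
    category = rng.choice(cats, size=design.n_features, p=probs)
    fold = np.asarray([CATEGORY_FOLD[c] for c in category])
    width = len(str(design.n_features))
    ids = [f"F{i + 1:0{width}d}" for i in range(design.n_features)]
    return SimTruth(ids, category, fold, category != "equal")


def draw_library_weights(
    design: SimDesign, n_per_group: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative library-size weights for each group.

    Normal around the per-group mean with the within-group sd, floored at
    ``lib_weight_floor`` to stay positive.
    """
    rng = _rng(seed, 2)
    m1, m2 = design.lib_weight_means
    w1 = rng.normal(m1, design.lib_weight_sd, size=n_per_group)
    w2 = rng.normal(m2, design.lib_weight_sd, size=n_per_group)
    floor = design.lib_weight_floor
    return np.maximum(w1, floor), np.maximum(w2, floor)


def simulate_counts(design: SimDesign, truth: SimTruth, seed: int = 0) -> SimOutput:
    """Draw the count matrix for a design and its truth assignment.

    Per feature i, a baseline mean ``mu_i`` is drawn once; the group-2 mean
    is ``mu_i * fold_change_i``; each sample's target mean is additionally
    scaled by its library weight; counts are NB(mean m, size r) with
    variance ``m + m^2 / r``.
    """
    if len(truth.feature_ids) != design.n_features:
        raise ConfigError("truth length does not match design n_features")
    rng = _rng(seed, 3)
    D, n = design.n_features, design.n_per_group

    mu = rng.lognormal(design.baseline_log_mean, design.baseline_log_sd, size=D)
    mu = np.maximum(mu, design.baseline_min)
    w1, w2 = draw_library_weights(design, n, seed)
    weights = np.concatenate([w1, w2])

    group_mean = np.column_stack([mu, mu * truth.fold_change])  # (D, 2)
    group_of = np.repeat([0, 1], n)
    m = group_mean[:, group_of] * weights[None, :]  # (D, 2n)

    if design.dispersion == "high":
        r = np.ones((D, 1))
    else:
        r = (mu / design.size_low_factor)[:, None]
    p = r / (r + m)
    values = rng.negative_binomial(np.broadcast_to(r, m.shape), p)

    width = len(str(n))
    sample_ids = [f"g1_s{j + 1:0{width}d}" for j in range(n)] + [
        f"g2_s{j + 1:0{width}d}" for j in range(n)
    ]
    groups = GroupAssignment(
        {s: ("group1" if g == 0 else "group2") for s, g in zip(sample_ids, group_of)}
    )
    counts = CountMatrix(values, list(truth.feature_ids), sample_ids)
    return SimOutput(counts, truth, groups, weights, design)


def simulate(design: SimDesign, seed: int = 0) -> SimOutput:
    """Convenience wrapper: assign truth, then draw counts, one seed."""
    return simulate_counts(design, assign_truth(design, seed), seed)


def subsample(
    sim: SimOutput,
    n_per_group: int,
    n_repeats: int = 20,
    n_features: int | None = None,
    seed: int = 0,
) -> list[SimOutput]:
    """Repeatedly sub-sample samples and features without replacement.

    Each repeat draws ``n_per_group`` samples per group and ``n_features``
    features (default: all) without replacement; truth and library weights
    are subset accordingly. Indices are drawn independently per repeat but
    the whole list is reproducible under the seed. Requesting all samples
    and all features returns datasets identical to the input.
    """
    design = sim.design
    if n_per_group > design.n_per_group:
        raise InputError(
            f"n_per_group={n_per_group} exceeds population size {design.n_per_group}"
        )
    D = sim.counts.n_features
    if n_features is None:
        n_features = D
    if n_features > D:
        raise InputError(f"n_features={n_features} exceeds available features {D}")

    group_cols = {
        g: np.flatnonzero(
            [sim.groups.labels[s] == g for s in sim.counts.sample_ids]
        )
        for g in sim.groups.group_names()
    }
    out: list[SimOutput] = []
    for rep in range(n_repeats):
        rng = _rng(seed, 4, rep)
        cols = np.sort(
            np.concatenate(
                [rng.choice(idx, size=n_per_group, replace=False) for idx in group_cols.values()]
            )
        )
        rows = np.sort(rng.choice(D, size=n_features, replace=False))
        sub_design = replace(design, n_features=n_features, n_per_group=n_per_group)
        out.append(
            SimOutput(
                sim.counts.subset(rows, cols),
                sim.truth.subset(rows),
                GroupAssignment(
                    {sim.counts.sample_ids[j]: sim.groups.labels[sim.counts.sample_ids[j]] for j in cols}
                ),
                sim.library_weights[cols],
                sub_design,
            )
        )
    return out
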