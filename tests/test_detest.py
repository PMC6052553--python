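"""Univariate tests, BH adjustment, and the expected-p-value procedure."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import codadiff as cd
from codadiff.detest import expected_de
from codadiff.logratio import all_features_reference
from codadiff.matrix import InputError, ParameterError


def bh_by_hand(p):
    """Step-up BH: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestWilcoxonP:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([1, 2, 3], [4, 5, 6], 0.1),  # extreme split of C(6,3)=20: p = 2/20
            ([1, 2], [3, 4], 1 / 3),  # extreme split of C(4,2)=6: p = 2/6
            ([1, 2], [1, 2], 1.0),  # identical samples, zero separation
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert cd.wilcoxon_p(a, b) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            cd.wilcoxon_p([1.0], [2.0, 3.0])


class TestWelchP:
    def test_degenerate_groups(self):
        assert cd.welch_p([0, 0], [0, 0]) == 1.0
        assert cd.welch_p([1, 2, 3, 4], [1, 2, 3, 4]) == 1.0
        assert cd.welch_p([5.0, 5.0], [7.0, 7.0]) < 1e-100  # constant but unequal

    def test_hand_computed_statistic(self):
        # means 11 vs 14, both variances 1, n=3 each:
        # t = -3 / sqrt(2/3), Welch-Satterthwaite df = 4
        t = -3 / math.sqrt(2 / 3)
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert cd.welch_p([10, 11, 12], [13, 14, 15]) == pytest.approx(expected, rel=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04, 0.03, 0.05], [0.04, 0.05, 0.05, 0.05]),
            ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
            ([0.02], [0.02]),
        ],
    )
    def test_worked_examples(self, p, expected):
        assert np.allclose(cd.bh_adjust(p), expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            cd.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_dominates_raw_p_and_matches_hand_step_up(self, p):
        q = cd.bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        assert np.allclose(q, bh_by_hand(p), atol=1e-12)


class TestRunDE:
    @pytest.mark.parametrize("n_per_group", [2, 3])
    def test_no_calls_possible_with_tiny_groups(self, n_per_group):
        # minimum attainable two-sided rank-sum p is 1/3 (n=2) or 0.1 (n=3)
        rng = np.random.default_rng(0)
        S = 2 * n_per_group
        counts = cd.CountMatrix(
            rng.poisson(100, size=(40, S)),
            [f"f{i}" for i in range(40)],
            [f"s{j}" for j in range(S)],
        )
        groups = cd.GroupAssignment({f"s{j}": "AB"[j // n_per_group] for j in range(S)})
        res = cd.run_de(counts, groups, "clr", n_instances=8, seed=1)
        assert res.called.sum() == 0
        assert res.wi_eBH.min() >= 0.1

    def test_single_instance_reduces_to_plain_bh(self, small_counts, small_groups):
        res = cd.run_de(small_counts, small_groups, "clr", n_instances=1, seed=6)
        mcs = cd.sample_instances(small_counts, 1, prior=0.5, seed=6)
        ts = cd.transform_instances(mcs, all_features_reference(small_counts), "clr")
        _, i1, i2 = small_groups.split(small_counts)
        p = np.array(
            [cd.wilcoxon_p(ts.values[0, f, i1], ts.values[0, f, i2]) for f in range(30)]
        )
        assert np.allclose(res.wi_ep, p)
        assert np.allclose(res.wi_eBH, cd.bh_adjust(p))

    def test_each_instance_bh_dominates_raw(self, small_counts, small_groups):
        # averaged adjusted values dominate averaged raw values because the
        # domination holds within every instance
        res = cd.run_de(small_counts, small_groups, "iqlr", n_instances=16, seed=2)
        assert np.all(res.wi_eBH >= res.wi_ep - 1e-12)
        assert np.all(res.we_eBH >= res.we_ep - 1e-12)

    def test_deterministic_under_seed(self, small_counts, small_groups):
        a = cd.run_de(small_counts, small_groups, "clr", n_instances=8, seed=3)
        b = cd.run_de(small_counts, small_groups, "clr", n_instances=8, seed=3)
        for field in ("wi_ep", "wi_eBH", "we_ep", "we_eBH", "effect_median_diff"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_welch_column_can_drive_calls(self, signal_sim):
        res = cd.run_de(
            signal_sim.counts, signal_sim.groups, "clr", n_instances=8, seed=4,
            call_column="we.eBH",
        )
        assert np.array_equal(res.called, res.we_eBH < 0.05)

    def test_malr_requires_reference(self, small_counts, small_groups):
        with pytest.raises(ParameterError):
            cd.run_de(small_counts, small_groups, "malr", n_instances=2, seed=0)
        with pytest.raises(InputError):
            cd.run_de(
                small_counts, small_groups, "malr", n_instances=2, seed=0,
                reference_features=["not-a-feature"],
            )

    def test_unknown_transform_rejected(self, small_counts, small_groups):
        with pytest.raises(ParameterError):
            cd.run_de(small_counts, small_groups, "alr", n_instances=2, seed=0)

    def test_tiny_group_rejected(self, small_counts):
        groups = cd.GroupAssignment(
            {f"s{j}": ("A" if j == 0 else "B") for j in range(10)}
        )
        with pytest.raises(InputError):
            cd.run_de(small_counts, groups, "clr", n_instances=2, seed=0)

    def test_calls_stable_under_sample_depth_scaling(self, signal_sim):
        # the log-ratio removes per-sample scale exactly at the transform
        # level; end to end, scaling a sample's counts still tightens its
        # Dirichlet posterior, so calls are near- but not bit-identical
        sim = signal_sim
        scaled = sim.counts.values.copy()
        scaled[:, 0] *= 10
        counts10 = cd.CountMatrix(scaled, sim.counts.feature_ids, sim.counts.sample_ids)
        res = cd.run_de(sim.counts, sim.groups, "clr", n_instances=8, seed=13)
        res10 = cd.run_de(counts10, sim.groups, "clr", n_instances=8, seed=13)
        assert (res.called == res10.called).mean() >= 0.97
        assert stats.spearmanr(res.wi_eBH, res10.wi_eBH).statistic > 0.99


def test_expected_de_metadata_echo(small_counts, small_groups):
    res = expected_de(
        small_counts, small_groups, all_features_reference(small_counts),
        name="clr", n_instances=4, prior=0.5, seed=0, threshold=0.05,
    )
    assert res.metadata["transform"] == "clr"
    assert res.metadata["n_instances"] == 4
    frame = res.to_frame()
    assert list(frame.columns) == [
        "feature_id", "wi.ep", "wi.eBH", "we.ep", "we.eBH", "effect.median.diff", "called",
    ]
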