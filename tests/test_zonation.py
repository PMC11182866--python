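"""Tests for CONISS clustering and broken-stick zone selection.

The oracle for the merge sequence recomputes every candidate fusion cost
from scratch (total within-cluster sum of squares of the merged block)
instead of using the incremental centroid update, and follows the same
greedy uppermost-tie policy.
"""

import numpy as np
import pandas as pd
import pytest

from corestrat import ConissZonation, broken_stick_zones, coniss, transform
from corestrat.zonation import broken_stick_expectation


def greedy_oracle(X):
    """Brute-force constrained clustering: at each step recompute the
    within-SS increase of every adjacent fusion directly from the raw
    samples of the merged block."""
    X = np.asarray(X, dtype=float)

    def within_ss(block):
        return float(((block - block.mean(axis=0)) ** 2).sum())

    clusters = [[i] for i in range(len(X))]
    ss = [0.0] * len(X)
    merges = []
    while len(clusters) > 1:
        costs = []
        for a in range(len(clusters) - 1):
            merged = clusters[a] + clusters[a + 1]
            costs.append(within_ss(X[merged]) - ss[a] - ss[a + 1])
        p = int(np.argmin(costs))   # uppermost on ties
        merges.append((p, costs[p], clusters[p][-1]))
        clusters[p] = clusters[p] + clusters.pop(p + 1)
        ss[p] = within_ss(X[clusters[p]])
        ss.pop(p + 1)
    return merges


class TestTransform:
    def test_center_only(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        out = transform(df)
        assert out["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_log_then_center(self):
        df = pd.DataFrame({"a": [1.0, np.e, np.e ** 2]})
        out = transform(df, log_vars=["a"])
        assert out["a"].tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_log_of_zero_without_offset_errors(self):
        df = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        with pytest.raises(ValueError, match="non-positive"):
            transform(df, log_vars=["a"])
        # with an offset it goes through
        transform(df, log_vars=["a"], log_offset=1.0)

    def test_unit_variance_scaling(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [10.0, 30.0, 50.0]})
        out = transform(df, scale_unit_variance=True)
        assert out.std(ddof=1).tolist() == pytest.approx([1.0, 1.0])


class TestConiss:
    def test_identical_samples_merge_at_zero(self):
        res = coniss(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert res.merge_sequence[0][1] == pytest.approx(0.0)

    def test_three_sample_oracle(self):
        # [0],[0],[10]: zeros merge first (increase 0), then the whole
        # series at the total SS of {0,0,10} = 66.67
        res = coniss(np.array([[0.0], [0.0], [10.0]]))
        increases = [m[1] for m in res.merge_sequence]
        assert increases[0] == pytest.approx(0.0)
        assert increases[1] == pytest.approx(200.0 / 3.0)
        assert res.total_ss == pytest.approx(200.0 / 3.0)

    def test_conservation_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(rng.integers(4, 30), rng.integers(1, 6)))
            res = coniss(X)
            assert np.sum(res.increments) == pytest.approx(
                res.total_ss, rel=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            got = coniss(X).merge_sequence
            want = greedy_oracle(X)
            assert [m[0] for m in got] == [m[0] for m in want]
            assert [m[2] for m in got] == [m[2] for m in want]
            np.testing.assert_allclose([m[1] for m in got],
                                       [m[1] for m in want], rtol=1e-9,
                                       atol=1e-12)

    def test_uppermost_tie_breaking(self):
        # two equal-cost candidate merges; the shallower pair must win
        res = coniss(np.array([[0.0], [1.0], [5.0], [6.0]]))
        assert res.merge_sequence[0][0] == 0

    def test_single_sample_errors(self):
        with pytest.raises(ValueError):
            coniss(np.array([[1.0]]))

    def test_labels_contiguous(self):
        X = np.vstack([np.zeros((5, 2)), np.ones((5, 2)) * 4])
        z = ConissZonation(n_zones=2).fit(X)
        assert z.labels_.tolist() == [0] * 5 + [1] * 5


class TestBrokenStick:
    def test_expectation_sums_to_one(self):
        # sum over k of e_k equals 1 plus e_1 missing: total of all n
        # pieces' expected shares is 1
        n = 12
        inv = 1.0 / np.arange(1, n + 1)
        full = np.cumsum(inv[::-1])[::-1] / n
        assert full.sum() == pytest.approx(1.0)
        assert np.allclose(broken_stick_expectation(n), full[1:])

    def test_identical_samples_one_zone(self):
        res = coniss(np.ones((10, 3)))
        n, bounds = broken_stick_zones(res)
        assert n == 1 and bounds == []

    def test_planted_shift_two_zones_boundary_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (30, 4))
        X[14:] += 5.0
        z = ConissZonation().fit(X)
        assert z.n_zones_ >= 2
        assert min(abs(b - 13) for b in z.boundaries_idx_) <= 1

    def test_pure_noise_mostly_one_zone(self):
        hits = 0
        for seed in range(40):
            X = np.random.default_rng(seed).normal(size=(37, 15))
            hits += ConissZonation().fit(X).n_zones_ == 1
        assert hits >= 36   # >= 90%

    def test_boundary_depths_are_midpoints(self):
        depths = np.array([0.5, 1.5, 2.5, 3.5])
        X = np.array([[0.0], [0.1], [8.0], [8.1]])
        z = ConissZonation(n_zones=2).fit(X, depths=depths)
        assert z.result_.boundary_depths(2) == pytest.approx([2.0])
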