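"""LOO prediction evaluation, distance reports, rank tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sstats

from conncca.connectome import Connectome, EdgeDataset, edge_index_for
from conncca.evaluation import (
    DistanceReport,
    intermodal_distance,
    intersubject_variability,
    loo_predict,
    paired_wilcoxon,
    ranksum_compare,
)
from conncca.spd import OrderCalibration, calibrate_order_normalization, dai
from conncca.synthetic import make_wishart_pairs

from conftest import random_invertible, random_spd


def _conns(mats, band=None):
    labels = [f"r{i}" for i in range(mats[0].shape[0])]
    return [
        Connectome(matrix=m, labels=labels, kind="covariance", band=band,
                   subject_id=f"sub-{i}")
        for i, m in enumerate(mats)
    ]


def brute_force_ranksum(x, y):
    """Enumerate every assignment of the pooled ranks to the first sample."""
    combined = np.concatenate([x, y])
    ranks = sstats.rankdata(combined)
    W = ranks[: len(x)].sum()
    sums = [sum(cmb) for cmb in itertools.combinations(ranks, len(x))]
    sums = np.asarray(sums)
    return min(1.0, 2 * min(np.mean(sums <= W + 1e-9), np.mean(sums >= W - 1e-9)))


def brute_force_signed_rank(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = sstats.rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    sums = [
        np.sum(np.compress(mask, ranks))
        for mask in itertools.product([0, 1], repeat=len(d))
    ]
    sums = np.asarray(sums)
    return min(1.0, 2 * min(np.mean(sums <= w + 1e-9), np.mean(sums >= w - 1e-9)))


class TestRanksum:
    def test_separated_samples_exact_p(self):
        res = ranksum_compare([1.0, 2, 3], [10.0, 11, 12])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)

    def test_identical_samples_not_significant(self):
        res = ranksum_compare([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.pvalue > 0.9

    def test_matches_brute_force_on_random_small_samples(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 13 - n1))
            x = np.round(rng.standard_normal(n1), 1)  # rounding induces ties
            y = np.round(rng.standard_normal(n2), 1)
            res = ranksum_compare(x, y)
            assert res.pvalue == pytest.approx(brute_force_ranksum(x, y), abs=1e-12)

    def test_matches_reference_normal_approximation(self, rng):
        for _ in range(30):
            x = rng.standard_normal(int(rng.integers(8, 30)))
            y = rng.standard_normal(int(rng.integers(8, 30)))
            res = ranksum_compare(x, y)
            ref = sstats.ranksums(x, y).pvalue
            assert res.pvalue == pytest.approx(ref, abs=1e-6)

    def test_accepts_distance_reports(self):
        a = DistanceReport(values=np.array([1.0, 2, 3]), condition="a")
        b = DistanceReport(values=np.array([4.0, 5, 6]), condition="b")
        assert 0 <= ranksum_compare(a, b).pvalue <= 1


class TestPairedWilcoxon:
    def test_consistent_signs_exact_p(self):
        a = np.array([7.0, 9, 11, 13, 15, 17])
        b = a - np.array([1.0, 2, 3, 4, 5, 6])
        res = paired_wilcoxon(a, b)
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.03125)

    def test_equal_samples_degenerate(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = paired_wilcoxon([1.0, 2, 3], [1.0, 2, 3])
        assert res.pvalue == 1.0

    def test_matches_brute_force_on_random_small_samples(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 13))
            x = rng.standard_normal(n)
            y = x + rng.standard_normal(n)
            res = paired_wilcoxon(x, y)
            assert res.pvalue == pytest.approx(
                brute_force_signed_rank(x, y), abs=1e-12
            )

    def test_matches_reference_normal_approximation(self, rng):
        for _ in range(30):
            n = int(rng.integers(15, 40))
            x = rng.standard_normal(n)
            y = x + 0.3 + rng.standard_normal(n)
            res = paired_wilcoxon(x, y)
            ref = sstats.wilcoxon(x, y, mode="approx", correction=False).pvalue
            assert res.pvalue == pytest.approx(ref, abs=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            paired_wilcoxon([1.0, 2], [1.0, 2, 3])


class TestDistanceReports:
    def test_intermodal_identical_sets_zero(self, rng):
        mats = [random_spd(4, rng) for _ in range(3)]
        rep = intermodal_distance(_conns(mats), _conns(mats))
        np.testing.assert_allclose(rep.values, 0.0, atol=1e-8)

    def test_intermodal_known_pair_distance(self, rng):
        A = [np.eye(4)]
        F = np.diag([np.e**2, 1.0, 1.0, 1.0])
        rep = intermodal_distance(_conns(A), _conns([F]))
        assert rep.values[0] == pytest.approx(2.0)

    def test_intermodal_affine_invariance(self, rng):
        mats_a = [random_spd(4, rng) for _ in range(3)]
        mats_b = [random_spd(4, rng) for _ in range(3)]
        T = random_invertible(4, rng)
        before = intermodal_distance(_conns(mats_a), _conns(mats_b)).values
        after = intermodal_distance(
            _conns([T @ m @ T.T for m in mats_a]),
            _conns([T @ m @ T.T for m in mats_b]),
        ).values
        np.testing.assert_allclose(before, after, atol=1e-8)

    def test_intersubject_pair_count_and_zeros(self, rng):
        mats = [random_spd(4, rng) for _ in range(5)]
        rep = intersubject_variability(_conns(mats))
        assert rep.values.size == 10
        same = intersubject_variability(_conns([np.eye(3)] * 4))
        np.testing.assert_allclose(same.values, 0.0, atol=1e-10)

    def test_intersubject_grows_with_subject_deviation(self, rng):
        meds = []
        for dev in (0.2, 1.5):
            mats = [
                np.eye(8) + dev * (lambda W: W - np.eye(8))(
                    random_spd(8, rng, 0.7, 1.4)
                )
                for _ in range(8)
            ]
            meds.append(np.median(intersubject_variability(_conns(mats)).values))
        assert meds[1] > meds[0]

    def test_normalized_report_scales_by_calibration(self, rng):
        rep = DistanceReport(values=np.array([2.0, 4.0]), condition="c")
        cal = OrderCalibration(slope=0.1, intercept=0.0, orders=[5, 10, 20])
        out = rep.normalize(cal, order=10)
        np.testing.assert_allclose(out.values, [2.0, 4.0])
        assert out.normalized


class TestLooPredict:
    def _edge_pair(self, rng, n=8, R=8, share=0.9):
        labels = [f"r{i}" for i in range(R)]
        m = R * (R - 1) // 2
        t = rng.normal(0, 0.03, size=(n, 3))
        dirs_x = np.linalg.qr(rng.standard_normal((m, 3)))[0]
        dirs_y = np.linalg.qr(rng.standard_normal((m, 3)))[0]
        X = 0.02 * rng.standard_normal((n, m)) + t @ dirs_x.T
        Y = 0.02 * rng.standard_normal((n, m)) + share * t @ dirs_y.T
        return (
            EdgeDataset(X, edge_index_for(labels)),
            EdgeDataset(Y, edge_index_for(labels)),
        )

    def test_one_distance_per_subject_per_direction(self, rng):
        X, Y = self._edge_pair(rng)
        grid = [(2.0, 2.0)]
        rep_yx, rep_xy = loo_predict(X, Y, grid, n_perm=10, seed=0)
        assert rep_yx.values.size == 8
        assert rep_xy.values.size == 8
        assert rep_yx.condition == "y_from_x"
        assert np.all(rep_yx.values >= 0)

    def test_needs_at_least_four_subjects(self, rng):
        X, Y = self._edge_pair(rng, n=3)
        with pytest.raises(ValueError, match="4 subjects"):
            loo_predict(X, Y, [(2.0, 2.0)], n_perm=10)

    def test_predicting_low_variability_side_is_easier(self, rng):
        # both modalities share a factor with equal loadings, but X carries
        # much more unshared subject variability than Y: predicting the
        # low-variability side (Y from X) gives smaller distances than the
        # reverse, mirroring the directional asymmetry the pipeline reports
        labels = [f"r{i}" for i in range(8)]
        m = 28
        t = rng.normal(0, 1.0, size=(10, 2))
        dx = np.linalg.qr(rng.standard_normal((m, 2)))[0]
        dy = np.linalg.qr(rng.standard_normal((m, 2)))[0]
        X = 0.06 * rng.standard_normal((10, m)) + 0.05 * t @ dx.T
        Y = 0.01 * rng.standard_normal((10, m)) + 0.05 * t @ dy.T
        Xd = EdgeDataset(X, edge_index_for(labels))
        Yd = EdgeDataset(Y, edge_index_for(labels))
        rep_yx, rep_xy = loo_predict(Xd, Yd, [(2.5, 2.5)], n_perm=10, seed=1)
        assert rep_yx.values.mean() < rep_xy.values.mean()


class TestOrderNormalizationComparability:
    def test_decoupled_baselines_comparable_across_orders(self):
        # unrelated Wishart "subjects" at 68 and 82 regions: after order
        # normalization the median pair distances agree within 10%
        cal = calibrate_order_normalization(range(10, 101, 10), n_pairs=40, seed=7)
        meds = {}
        for order in (68, 82):
            pairs = make_wishart_pairs(order, 2 * order, 60, seed=order)
            meds[order] = np.median(
                [dai(P, G) / cal.divisor(order) for P, G in pairs]
            )
        assert abs(meds[82] - meds[68]) / meds[68] < 0.10
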