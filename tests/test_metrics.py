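"""Residual metrics: hand arithmetic, brute-force oracles, invariants."""

import numpy as np
import pytest
from scipy import stats

from diffsurrogate import (
    field_pdf,
    histogram_intersection,
    relative_residual_map,
    residual_map,
    slice_aggregate,
    slice_statistics,
    summarize_residuals,
)


class TestResidualMap:
    def test_equal_arrays_give_zero(self, rng):
        y = rng.random((3, 5, 5))
        assert not residual_map(y, y).any()

    def test_constant_offset(self):
        y = np.full((4, 4), 0.3)
        assert residual_map(y + 0.1, y) == pytest.approx(0.1)

    def test_crafted_pair_matches_hand_arithmetic(self):
        target = np.array([[0.0, 0.5, 1.0], [0.2, 0.4, 0.6], [0.9, 0.1, 0.3]])
        pred = np.array([[0.1, 0.5, 0.8], [0.0, 0.5, 0.6], [1.0, 0.0, 0.35]])
        expected = np.array([[0.1, 0.0, 0.2], [0.2, 0.1, 0.0], [0.1, 0.1, 0.05]])
        assert residual_map(pred, target) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            residual_map(np.zeros((2, 2)), np.zeros((2, 3)))


class TestRelativeResidual:
    def test_zero_target_is_fully_masked(self):
        rel = relative_residual_map(np.full((3, 3), 0.2), np.zeros((3, 3)))
        assert rel.mask.all()
        assert rel.count() == 0

    def test_simple_ratio(self):
        rel = relative_residual_map(np.array([0.45]), np.array([0.5]))
        assert rel[0] == pytest.approx(0.1, abs=1e-12)

    def test_matches_bruteforce_masked_division(self, rng):
        target = rng.random((6, 6))
        pred = target + rng.normal(0, 0.05, (6, 6))
        floor = 0.3
        rel = relative_residual_map(pred, target, floor=floor)
        for i in range(6):
            for j in range(6):
                if target[i, j] < floor:
                    assert rel.mask[i, j]
                else:
                    assert rel[i, j] == abs(target[i, j] - pred[i, j]) / target[i, j]
        assert np.isfinite(rel.filled(0.0)).all()


class TestSummary:
    def test_identical_sets_give_zeros(self, rng):
        y = rng.random((4, 8, 8))
        assert summarize_residuals(y, y) == (0.0, 0.0, 0.0)

    def test_order_statistics_of_a_known_pool(self):
        # 99 residuals of 0.01 and one of 1.0
        target = np.zeros(100)
        pred = np.full(100, 0.01)
        pred[-1] = 1.0
        mean, p99, mx = summarize_residuals(pred, target)
        assert mean == pytest.approx(0.0199, abs=1e-12)
        assert mx == 1.0
        # linear interpolation between the 98th and 99th order statistics:
        # fractional index 0.99 * 99 = 98.01
        assert p99 == pytest.approx(0.01 + 0.01 * (1.0 - 0.01), abs=1e-12)

    def test_constant_residual(self):
        mean, p99, mx = summarize_residuals(np.full((2, 3, 3), 0.7), np.full((2, 3, 3), 0.5))
        for v in (mean, p99, mx):
            assert v == pytest.approx(0.2, abs=1e-12)

    def test_mean_le_p99_le_max_always(self, rng):
        for _ in range(20):
            pred = rng.random((3, 7, 7))
            target = rng.random((3, 7, 7))
            mean, p99, mx = summarize_residuals(pred, target)
            assert mean <= p99 <= mx

    def test_permutation_invariance(self, rng):
        pred, target = rng.random((5, 4, 4)), rng.random((5, 4, 4))
        perm = rng.permutation(5)
        a = summarize_residuals(pred, target)
        b = summarize_residuals(pred[perm], target[perm])
        # up to float summation order in the mean
        assert a == pytest.approx(b, rel=1e-12)


class TestSliceStatistics:
    def test_all_low_values_populate_only_the_first_slice(self):
        target = np.full((2, 4, 4), 0.05)
        pred = target + 0.01
        means, stds, counts = slice_statistics(pred, target)
        assert counts[0] == 32 and counts[1:].sum() == 0
        assert means[0] == pytest.approx(0.01)
        assert np.isnan(means[1:]).all()

    def test_two_pixel_binning(self):
        target = np.array([0.05, 0.15])
        pred = np.array([0.06, 0.18])
        means, _, counts = slice_statistics(pred, target)
        assert means[0] == pytest.approx(0.01)
        assert means[1] == pytest.approx(0.03)
        assert counts[0] == counts[1] == 1

    def test_source_value_lands_in_the_last_slice(self):
        means, _, counts = slice_statistics(np.array([0.9]), np.array([1.0]))
        assert counts[9] == 1

    def test_matches_bruteforce_binning(self, rng):
        target = rng.random((3, 8, 8))
        pred = target + rng.normal(0, 0.1, target.shape)
        means, stds, counts = slice_statistics(pred, target)
        res = np.abs(target - pred).ravel()
        tv = target.ravel()
        for k in range(10):
            lo, hi = k / 10, (k + 1) / 10
            sel = (tv >= lo) & ((tv < hi) if k < 9 else (tv <= 1.0))
            assert counts[k] == sel.sum()
            if sel.any():
                assert means[k] == pytest.approx(res[sel].mean(), rel=1e-12)
                assert stds[k] == pytest.approx(res[sel].std(), rel=1e-9)

    def test_single_slice_reproduces_the_pooled_mean(self, rng):
        pred, target = rng.random((2, 6, 6)), rng.random((2, 6, 6))
        means, _, counts = slice_statistics(pred, target, n_slices=1)
        pooled_mean, _, _ = summarize_residuals(pred, target)
        assert counts[0] == target.size
        assert means[0] == pytest.approx(pooled_mean, rel=1e-12)


class TestSliceAggregate:
    def test_single_populated_slice(self):
        means = np.array([np.nan, 0.2] + [np.nan] * 8)
        stds = np.array([np.nan, 0.05] + [np.nan] * 8)
        agg = slice_aggregate(means, stds)
        assert agg["avg_slice_mean"] == agg["max_slice_mean"] == pytest.approx(0.2)

    def test_two_slices(self):
        means = np.array([0.1, 0.3])
        stds = np.array([0.02, 0.01])
        agg = slice_aggregate(means, stds)
        assert agg["avg_slice_mean"] == pytest.approx(0.2)
        assert agg["max_slice_mean"] == pytest.approx(0.3)
        assert agg["avg_slice_std"] == pytest.approx(0.015)

    def test_matches_recomputation_from_raw_pixels(self, rng):
        target = rng.random((2, 10, 10))
        pred = target + rng.normal(0, 0.05, target.shape)
        means, stds, counts = slice_statistics(pred, target)
        agg = slice_aggregate(means, stds)
        ok = counts > 0
        assert agg["avg_slice_mean"] == pytest.approx(means[ok].mean(), rel=1e-12)
        assert agg["max_slice_std"] == pytest.approx(stds[ok].max(), rel=1e-12)

    def test_all_empty_is_an_error(self):
        with pytest.raises(ValueError):
            slice_aggregate(np.full(10, np.nan), np.full(10, np.nan))


class TestFieldPdf:
    def test_all_zero_images_put_mass_in_the_first_bin(self):
        h = field_pdf(np.zeros((3, 8, 8)), n_bins=10)
        assert h.density[0] == pytest.approx(10.0)  # all density in width-0.1 bin
        assert h.density[1:] == pytest.approx(0.0)

    def test_density_integrates_to_one(self, rng):
        h = field_pdf(rng.random((5, 16, 16)), n_bins=37)
        assert np.sum(h.density * np.diff(h.bin_edges)) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_samples_are_flat(self):
        rng = np.random.default_rng(8)
        h = field_pdf(rng.random(100_000), n_bins=100)
        counts = h.density * 1000  # density * bin width * n
        _, p = stats.chisquare(counts)
        assert p > 1e-6

    def test_out_of_range_values_are_clipped_and_counted(self):
        h = field_pdf(np.array([-0.1, 0.5, 1.2]), n_bins=10)
        assert h.n_clipped == 2

    def test_intersection_of_identical_histograms_is_one(self, rng):
        x = rng.random(5000)
        a, b = field_pdf(x), field_pdf(x.copy())
        assert histogram_intersection(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_intersection_of_disjoint_histograms_is_zero(self):
        a = field_pdf(np.full(100, 0.1))
        b = field_pdf(np.full(100, 0.9))
        assert histogram_intersection(a, b) == pytest.approx(0.0, abs=1e-12)
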