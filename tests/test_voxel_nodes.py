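"""Voxel-pair correlation, threshold search and representative signals."""

import numpy as np
import pytest

from hanet.voxel_nodes import (
    PairCorrelationSet,
    VoxelSeriesSet,
    conventional_series,
    enumerate_pairs,
    extract_voxel_series,
    find_threshold,
    pair_correlation,
    n_cross_roi_pairs,
    representative_series,
)

from oracles import pearson_direct, threshold_scan


def make_vset(series, roi):
    series = np.asarray(series, float)
    roi = np.asarray(roi, int)
    coords = np.column_stack([np.arange(len(roi)), np.zeros(len(roi), int), np.zeros(len(roi), int)])
    return VoxelSeriesSet(series, roi, coords, np.unique(roi))


def make_pcs(entries):
    """entries: list of (va, vb, roi_a, roi_b, r)."""
    va, vb, ra, rb, r = (np.array(x) for x in zip(*entries))
    return PairCorrelationSet(va, vb, ra, rb, r.astype(float))


class TestPairCorrelation:
    def test_worked_example(self):
        assert pair_correlation([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8, abs=1e-12)

    def test_negative_correlation_deemed_zero(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pair_correlation(x, -x) == 0.0

    def test_auto_correlation_deemed_zero(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        assert pair_correlation(x, x) == 0.0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pair_correlation([1, 1, 1], [1, 2, 3])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.standard_normal((2, 30))
        expected = max(pearson_direct(x, y), 0.0)
        assert pair_correlation(x, y) == pytest.approx(expected, abs=1e-12)


class TestExtractVoxelSeries:
    def test_row_count_equals_labelled_voxels(self, small_parcellation, small_volume):
        vset = extract_voxel_series(small_volume, small_parcellation)
        assert vset.n_voxels == int((small_parcellation.label_volume > 0).sum())
        assert np.all(vset.roi_of_voxel > 0)

    def test_dimension_mismatch_names_both_shapes(self, small_parcellation):
        bad = np.zeros((3, 3, 3, 10))
        with pytest.raises(ValueError, match=r"\(3, 3, 3\)"):
            extract_voxel_series(bad, small_parcellation)

    def test_noise_free_rows_identical_within_roi(self, small_parcellation, noise_free_volume):
        vset = extract_voxel_series(noise_free_volume, small_parcellation)
        for label in small_parcellation.labels:
            rows = vset.series[vset.roi_of_voxel == label]
            assert np.allclose(rows, rows[0])

    def test_constant_voxels_excluded_and_counted(self, two_roi_parcellation):
        t = 12
        rng = np.random.default_rng(0)
        vol = rng.standard_normal(two_roi_parcellation.shape + (t,))
        coords = np.argwhere(two_roi_parcellation.label_volume > 0)
        vol[tuple(coords[0])] = 7.0  # one flat voxel
        vset = extract_voxel_series(vol, two_roi_parcellation)
        assert vset.n_constant_excluded == 1
        assert vset.n_voxels == len(coords) - 1


class TestEnumeratePairs:
    def test_exhaustive_count_is_product_over_roi_pairs(self):
        rng = np.random.default_rng(1)
        vset = make_vset(rng.standard_normal((6, 20)), [1, 1, 1, 2, 2, 2])
        pcs = enumerate_pairs(vset, "exhaustive")
        assert pcs.n_pairs == 9
        assert n_cross_roi_pairs(vset) == 9
        assert np.all(pcs.roi_a != pcs.roi_b)

    def test_random_saturating_request_returns_all_pairs(self):
        rng = np.random.default_rng(2)
        vset = make_vset(rng.standard_normal((6, 20)), [1, 1, 1, 2, 2, 2])
        pcs = enumerate_pairs(vset, "random", n_pairs=9, seed=3)
        ex = enumerate_pairs(vset, "exhaustive")
        got = set(zip(pcs.voxel_a.tolist(), pcs.voxel_b.tolist()))
        want = set(zip(ex.voxel_a.tolist(), ex.voxel_b.tolist()))
        assert got == want

    def test_random_mode_deterministic_for_seed(self):
        rng = np.random.default_rng(4)
        vset = make_vset(rng.standard_normal((12, 20)), [1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
        a = enumerate_pairs(vset, "random", n_pairs=10, seed=5)
        b = enumerate_pairs(vset, "random", n_pairs=10, seed=5)
        assert np.array_equal(a.voxel_a, b.voxel_a)
        assert np.array_equal(a.voxel_b, b.voxel_b)
        assert np.array_equal(a.r, b.r)

    def test_over_request_states_maximum(self):
        rng = np.random.default_rng(6)
        vset = make_vset(rng.standard_normal((4, 20)), [1, 1, 2, 2])
        with pytest.raises(ValueError, match="4"):
            enumerate_pairs(vset, "random", n_pairs=99, seed=0)

    def test_zeroing_rule_bounds_r(self, small_parcellation, small_volume):
        vset = extract_voxel_series(small_volume, small_parcellation)
        pcs = enumerate_pairs(vset, "exhaustive")
        assert pcs.r.min() >= 0.0
        assert pcs.r.max() <= 1.0


class TestFindThreshold:
    def test_single_level_construction(self):
        pcs = make_pcs([(0, 2, 1, 2, 0.9), (1, 3, 1, 2, 0.9)])
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        assert thr.feasible
        assert thr.r_star == pytest.approx(0.9)

    def test_weakest_roi_sets_threshold(self):
        pcs = make_pcs(
            [(0, 2, 1, 2, 0.9), (2, 4, 2, 3, 0.9), (4, 0, 3, 1, 0.9), (5, 1, 4, 1, 0.3)]
        )
        thr = find_threshold(pcs, np.array([1, 2, 3, 4]), grid_step=0.1)
        assert thr.r_star == pytest.approx(0.3)

    def test_all_zero_correlations_infeasible(self):
        pcs = make_pcs([(0, 2, 1, 2, 0.0), (1, 3, 1, 2, 0.0)])
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        assert not thr.feasible
        assert thr.r_star is None

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_rois = int(rng.integers(2, 6))
        entries = []
        vid = 0
        for ra in range(1, n_rois + 1):
            for rb in range(ra + 1, n_rois + 1):
                for _ in range(int(rng.integers(1, 4))):
                    entries.append((vid, vid + 1, ra, rb, float(np.round(rng.uniform(0, 1), 3))))
                    vid += 2
        pcs = make_pcs(entries)
        labels = np.arange(1, n_rois + 1)
        step = float(rng.choice([0.01, 0.05, 0.1]))
        thr = find_threshold(pcs, labels, grid_step=step)
        expected = threshold_scan(
            [(ra, rb, va, vb, r) for va, vb, ra, rb, r in entries], labels, step
        )
        if expected is None:
            assert not thr.feasible
        else:
            assert thr.feasible
            assert thr.r_star == pytest.approx(expected, abs=1e-9)

    def test_effective_roi_set_monotone_in_threshold(self):
        rng = np.random.default_rng(33)
        entries = [
            (2 * i, 2 * i + 1, int(rng.integers(1, 5)), int(rng.integers(5, 9)), float(rng.uniform(0, 1)))
            for i in range(40)
        ]
        labels = np.arange(1, 9)

        def rois_ok(t):
            eff = {int(l): 0 for l in labels}
            for va, vb, ra, rb, r in entries:
                if r > 0 and r >= t:
                    eff[ra] += 1
                    eff[rb] += 1
            return {l for l, c in eff.items() if c >= 1}

        prev = None
        for t in np.arange(0.95, 0.0, -0.05):
            cur = rois_ok(t)
            if prev is not None:
                assert prev.issubset(cur)
            prev = cur


class TestRepresentativeSeries:
    def test_single_effective_voxel_is_identity(self):
        series = np.array([[1.0, 2.0, 3.0], [9.0, 8.0, 7.0]])
        vset = make_vset(series, [1, 2])
        pcs = make_pcs([(0, 1, 1, 2, 0.8)])
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        sig = representative_series(pcs, thr, vset)
        assert np.allclose(sig.signals[0], series[0])
        assert np.allclose(sig.signals[1], series[1])

    def test_pair_count_weighted_blend(self):
        # voxel a: 3 surviving pairs of series [1,1]; voxel b: 1 pair of [5,5]
        series = np.array(
            [[1.0, 1.0], [5.0, 5.0], [0.0, 1.0], [1.0, 0.0], [0.5, 1.0], [1.0, 0.5]]
        )
        roi = np.array([1, 1, 2, 2, 2, 2])
        vset = make_vset(series, roi)
        pcs = make_pcs(
            [(0, 2, 1, 2, 0.9), (0, 3, 1, 2, 0.9), (0, 4, 1, 2, 0.9), (1, 5, 1, 2, 0.9)]
        )
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        sig = representative_series(pcs, thr, vset)
        assert np.allclose(sig.signals[0], [2.0, 2.0])

    def test_equal_pair_counts_give_arithmetic_mean(self):
        series = np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0], [3.0, 3.0]])
        vset = make_vset(series, [1, 1, 2, 2])
        pcs = make_pcs([(0, 2, 1, 2, 0.8), (1, 3, 1, 2, 0.8)])
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        sig = representative_series(pcs, thr, vset)
        assert np.allclose(sig.signals[0], [1.0, 1.0])

    def test_weights_sum_to_one_and_envelope(self, small_parcellation, small_volume):
        vset = extract_voxel_series(small_volume, small_parcellation)
        pcs = enumerate_pairs(vset, "exhaustive")
        thr = find_threshold(pcs, vset.roi_labels)
        sig = representative_series(pcs, thr, vset)
        for row, label in enumerate(sig.roi_labels):
            voxels = vset.series[vset.roi_of_voxel == label]
            assert np.all(sig.signals[row] <= voxels.max(axis=0) + 1e-12)
            assert np.all(sig.signals[row] >= voxels.min(axis=0) - 1e-12)

    def test_infeasible_threshold_rejected(self):
        vset = make_vset(np.random.default_rng(0).standard_normal((2, 10)), [1, 2])
        pcs = make_pcs([(0, 1, 1, 2, 0.0)])
        thr = find_threshold(pcs, np.array([1, 2]), grid_step=0.1)
        with pytest.raises(ValueError, match="infeasible"):
            representative_series(pcs, thr, vset)


class TestConventionalSeries:
    def test_two_voxel_mean(self):
        series = np.array([[0.0, 2.0], [2.0, 0.0], [1.0, 5.0]])
        vset = make_vset(series, [1, 1, 2])
        sig = conventional_series(vset)
        assert np.allclose(sig.signals[0], [1.0, 1.0])
        assert np.allclose(sig.signals[1], [1.0, 5.0])

    def test_noise_free_matches_highly_available(self, small_parcellation, noise_free_volume):
        vset = extract_voxel_series(noise_free_volume, small_parcellation)
        pcs = enumerate_pairs(vset, "exhaustive")
        thr = find_threshold(pcs, vset.roi_labels)
        han = representative_series(pcs, thr, vset)
        mean = conventional_series(vset)
        assert np.allclose(han.signals, mean.signals, atol=1e-10)
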