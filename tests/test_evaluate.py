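"""Evaluation methodology: MPE, success rates, capture-range binning,
divergence detection, preference tallying, exact signed-rank test."""

import numpy as np
import pytest

from angioreg.evaluate import (
    CaptureRangeBin,
    CaptureRangeRecord,
    PreferenceRecord,
    capture_range_histogram,
    divergence_point,
    mpe,
    signed_rank_test,
    success_rate,
    tally_preferences,
)
from angioreg.geometry import CArmGeometry, VolumeGrid
from angioreg.se3 import RigidTransform, exp


@pytest.fixture(scope="module")
def geom():
    return CArmGeometry(source_to_detector=1000.0, detector_rows=128, detector_cols=128, pixel_spacing=2.0)


@pytest.fixture(scope="module")
def box_volume():
    return VolumeGrid.centered(np.ones((20, 20, 20), np.float32), spacing=3.0)


def bruteforce_mpe(t_ref, t_reg, volume, geom):
    """Independent reimplementation: explicit homogeneous projection of the
    bounding-box corners through a pinhole at the source."""
    d, h, w = volume.values.shape
    corners = np.array(
        [[i, j, k, 1.0] for i in (0, d - 1) for j in (0, h - 1) for k in (0, w - 1)]
    )
    world = (volume.voxel_to_world @ corners.T)[:3].T
    out = []
    for t in (t_ref, t_reg):
        m = t.matrix()
        cam = (m @ np.c_[world, np.ones(8)].T)[:3].T
        src_z = -geom.source_to_isocenter
        scale = geom.source_to_detector / (cam[:, 2] - src_z)
        x = cam[:, 0] * scale
        y = cam[:, 1] * scale
        pr, pc = geom.principal_point
        out.append(np.stack([y / geom.pixel_spacing + pr, x / geom.pixel_spacing + pc], axis=1))
    return float(np.linalg.norm(out[0] - out[1], axis=1).mean())


class TestMpe:
    def test_zero_at_equal_poses(self, geom, box_volume):
        t = exp(np.array([0.1, -0.2, 0.05, 10, 5, -3]))
        assert mpe(t, t, box_volume, geom) == 0.0

    def test_symmetry(self, geom, box_volume):
        rng = np.random.default_rng(1)
        a = exp(np.concatenate([rng.normal(size=3) * 0.1, rng.normal(size=3) * 10]))
        b = exp(np.concatenate([rng.normal(size=3) * 0.1, rng.normal(size=3) * 10]))
        assert mpe(a, b, box_volume, geom) == pytest.approx(mpe(b, a, box_volume, geom), rel=1e-12)

    def test_inplane_translation_magnification_law(self, geom, box_volume):
        """Detector-parallel shift of D mm: MPE = D * magnification /
        pixel_spacing within 1% (exact in the small-depth limit)."""
        d_mm = 8.0
        t = exp(np.array([0, 0, 0, d_mm, 0, 0]))
        expected = d_mm * geom.magnification / geom.pixel_spacing
        assert mpe(RigidTransform(), t, box_volume, geom) == pytest.approx(expected, rel=0.01)

    def test_mm_variant_scales_by_pixel_spacing(self, geom, box_volume):
        t = exp(np.array([0.02, 0, 0, 5, 3, 0]))
        px = mpe(RigidTransform(), t, box_volume, geom, unit="px")
        mm = mpe(RigidTransform(), t, box_volume, geom, unit="mm")
        assert mm == pytest.approx(px * geom.pixel_spacing, rel=1e-12)

    def test_matches_bruteforce_oracle_on_random_pose_pairs(self, geom, box_volume):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = exp(np.concatenate([rng.normal(size=3) * 0.15, rng.normal(size=3) * 15]))
            b = exp(np.concatenate([rng.normal(size=3) * 0.15, rng.normal(size=3) * 15]))
            assert mpe(a, b, box_volume, geom) == pytest.approx(
                bruteforce_mpe(a, b, box_volume, geom), rel=1e-9
            )

    def test_explicit_fiducial_points_override_corners(self, geom, box_volume):
        t = exp(np.array([0, 0, 0, 4.0, 0, 0]))
        at_iso = mpe(RigidTransform(), t, box_volume, geom, points=np.zeros((1, 3)))
        assert at_iso == pytest.approx(4.0 * geom.magnification / geom.pixel_spacing, rel=1e-12)

    def test_corner_behind_source_raises(self, geom, box_volume):
        behind = exp(np.array([0, 0, 0, 0, 0, -2 * geom.source_to_isocenter]))
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="behind"):
                mpe(RigidTransform(), behind, box_volume, geom)


class TestSuccessRate:
    def test_fourteen_of_twenty_is_seventy_percent(self):
        mpes = [1.0] * 14 + [9.0] * 6
        assert success_rate(mpes, threshold=5.0) == pytest.approx(0.70)

    def test_thirtyseven_of_ninetyfour(self):
        mpes = [2.0] * 37 + [80.0] * 57
        assert success_rate(mpes, threshold=5.0) == pytest.approx(37 / 94)

    def test_none_below_threshold(self):
        assert success_rate([7.0, 9.0], 5.0) == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        mpes = rng.uniform(0, 50, 200)
        rates = [success_rate(mpes, t) for t in np.linspace(1, 60, 30)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            success_rate([], 5.0)


def records_from(before, after):
    return [CaptureRangeRecord(b, a) for b, a in zip(before, after)]


class TestCaptureRange:
    def test_equal_count_bins(self):
        rng = np.random.default_rng(4)
        recs = records_from(rng.uniform(0, 60, 100), rng.uniform(0, 20, 100))
        bins = capture_range_histogram(recs, 10)
        assert [b.count for b in bins] == [10] * 10
        assert sum(b.count for b in bins) == 100
        # contiguous, ordered in mpe_before
        for a, b in zip(bins, bins[1:]):
            assert a.hi <= b.lo

    def test_remainder_spread_over_leading_bins(self):
        recs = records_from(range(13), range(13))
        bins = capture_range_histogram(recs, 4)
        assert [b.count for b in bins] == [4, 3, 3, 3]

    def test_identity_registration_medians(self):
        vals = np.linspace(1, 30, 30)
        bins = capture_range_histogram(records_from(vals, vals), 5)
        for b in bins:
            assert b.lo <= b.median_after <= b.hi

    def test_hand_computed_medians_on_30_records(self):
        """Sort-and-slice oracle: 30 records, 3 bins of 10, medians by hand."""
        before = np.arange(30.0)  # already sorted
        after = np.array([5, 1, 3, 9, 7, 2, 8, 4, 6, 0,  # bin 1: median 4.5
                          15, 11, 13, 19, 17, 12, 18, 14, 16, 10,  # bin 2: 14.5
                          25, 21, 23, 29, 27, 22, 28, 24, 26, 20], float)  # bin 3: 24.5
        bins = capture_range_histogram(records_from(before, after), 3)
        assert [b.median_after for b in bins] == [4.5, 14.5, 24.5]

    def test_fewer_records_than_bins_raises(self):
        with pytest.raises(ValueError):
            capture_range_histogram(records_from([1, 2], [1, 2]), 3)


class TestDivergencePoint:
    def make_bins(self, medians):
        return [CaptureRangeBin(lo=10.0 * i, hi=10.0 * i + 9, median_after=m, count=10) for i, m in enumerate(medians)]

    def test_no_divergence_is_infinite(self):
        assert divergence_point(self.make_bins([1, 2, 3]), success_level=5) == np.inf

    def test_first_sustained_exceedance(self):
        bins = self.make_bins([2, 3, 4, 8, 9, 12])
        assert divergence_point(bins, success_level=5) == bins[3].lo

    def test_transient_spike_is_not_divergence(self):
        bins = self.make_bins([2, 9, 3, 4, 8, 12])
        assert divergence_point(bins, success_level=5) == bins[4].lo


class TestPreferences:
    def test_42_comparison_slots(self):
        """14 registrations x 3 method-pair types."""
        pairs = [("three_stage", "two_stage"), ("three_stage", "reference"), ("two_stage", "reference")]
        recs = [PreferenceRecord(l, r, 3) for l, r in pairs for _ in range(14)]
        tally = tally_preferences(recs)
        assert tally.n_comparisons == 42

    def test_all_ties(self):
        recs = [PreferenceRecord("a", "b", 3) for _ in range(10)]
        tally = tally_preferences(recs)
        assert tally.ties == 10
        assert all(v == 0 for v in tally.preferred.values())
        assert tally.p_values[("a", "b")] == pytest.approx(1.0)

    def test_preference_arithmetic(self):
        """13 + 9 + 6 preferences out of 42 comparisons leaves 14 ties."""
        recs = []
        recs += [PreferenceRecord("three_stage", "two_stage", 1)] * 8
        recs += [PreferenceRecord("three_stage", "two_stage", 4)] * 4
        recs += [PreferenceRecord("three_stage", "two_stage", 3)] * 2
        recs += [PreferenceRecord("three_stage", "reference", 2)] * 5
        recs += [PreferenceRecord("three_stage", "reference", 5)] * 3
        recs += [PreferenceRecord("three_stage", "reference", 3)] * 6
        recs += [PreferenceRecord("two_stage", "reference", 1)] * 5
        recs += [PreferenceRecord("two_stage", "reference", 4)] * 3
        recs += [PreferenceRecord("two_stage", "reference", 3)] * 6
        tally = tally_preferences(recs)
        assert tally.n_comparisons == 42
        assert tally.preferred["three_stage"] == 13
        assert tally.preferred["two_stage"] == 9
        assert tally.preferred["reference"] == 6
        assert tally.ties == 42 - (13 + 9 + 6) == 14

    def test_invalid_score_rejected(self):
        with pytest.raises(ValueError):
            PreferenceRecord("a", "b", 6)


class TestSignedRank:
    def test_exact_null_for_n3_matches_enumeration(self):
        """All 8 sign assignments of 3 distinct ranks enumerate the null."""
        scores = [4, 5, 4]  # diffs +1, +2, +1 -> ranks 1.5, 3, 1.5
        p = signed_rank_test(scores)
        # enumerate: W+ over all sign choices of |d| = (1,2,1)
        import itertools

        ranks = np.array([1.5, 3.0, 1.5])
        w_obs = ranks.sum()  # all positive
        ws = [sum(r for r, s in zip(ranks, signs) if s > 0) for signs in itertools.product([-1, 1], repeat=3)]
        mu = ranks.sum() / 2
        expected = np.mean([abs(w - mu) >= abs(w_obs - mu) - 1e-12 for w in ws])
        assert p == pytest.approx(expected)

    def test_matches_scipy_exact_without_ties(self):
        from scipy.stats import wilcoxon

        diffs = np.array([1.0, -2.0, 3.0, -4.0, 5.0, 6.0, -7.0, 8.0])
        p_ours = signed_rank_test(diffs + 3.0)  # centered at 3 inside
        p_scipy = wilcoxon(diffs, alternative="two-sided", method="exact").pvalue
        assert p_ours == pytest.approx(p_scipy, abs=1e-12)

    def test_all_zero_diffs(self):
        assert signed_rank_test([3, 3, 3]) == 1.0

    def test_strong_preference_is_significant(self):
        assert signed_rank_test([5] * 10) < 0.01
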