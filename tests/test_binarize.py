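import numpy as np
import pytest

from retseg import (ThresholdPair, binarize_vessels, compute_double_thresholds,
                    morphological_reconstruction)
from retseg.exceptions import DegenerateImageError, ParameterError

from oracles import brute_area_filter, brute_reconstruction


class TestComputeDoubleThresholds:
    def test_mean_minus_kstd_candidate_dark_tail(self):
        """Printed dark-vessel form: mean 0.5, std 0.5 -> candidate 0.15."""
        r = np.zeros((4, 4))
        r[:2] = 1.0
        fov = np.ones((4, 4), bool)
        t = compute_double_thresholds(r, fov, k_std=0.7, tail="dark")
        assert min(t.t_low, t.t_high) == pytest.approx(0.15) or \
            t.t_low == pytest.approx(0.15)
        assert t.t_low == pytest.approx(0.15)

    def test_bright_tail_mirrors_candidate(self):
        r = np.zeros((4, 4))
        r[:2] = 1.0
        fov = np.ones((4, 4), bool)
        t = compute_double_thresholds(r, fov, k_std=0.7, tail="bright")
        assert t.t_high == pytest.approx(0.85)

    def test_kstd_zero_uniform_gradient_collapses(self):
        # on a linear ramp every interior pixel has the same gradient, so
        # every FOV pixel is an "edge" pixel, the edge candidate equals the
        # FOV mean, and with k_std = 0 both thresholds coincide at the mean
        # exactly representable step (1/32) so the Sobel magnitude is
        # bit-identical across the interior and every pixel ties as "edge"
        r = np.broadcast_to(np.arange(20) / 32.0, (20, 20)).copy()
        fov = np.zeros((20, 20), bool)
        fov[3:-3, 3:-3] = True  # clear of Sobel border effects
        t = compute_double_thresholds(r, fov, k_std=0.0)
        assert t.t_low == pytest.approx(t.t_high, abs=1e-9)
        assert t.t_low == pytest.approx(r[fov].mean(), abs=1e-9)

    def test_ordering_invariant_on_response(self, small_run):
        seg, record = small_run
        assert record.thresholds["t_low"] <= record.thresholds["t_high"]

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            compute_double_thresholds(np.full((8, 8), 0.5), np.ones((8, 8), bool))

    def test_inverted_pair_rejected(self):
        with pytest.raises(ParameterError):
            ThresholdPair(t_low=0.8, t_high=0.2)


class TestMorphologicalReconstruction:
    def test_empty_marker_gives_empty(self):
        mask = np.ones((5, 5), bool)
        out = morphological_reconstruction(np.zeros((5, 5), bool), mask)
        assert not out.any()

    def test_marker_equals_mask_fixpoint(self, rng):
        mask = rng.random((8, 8)) > 0.5
        np.testing.assert_array_equal(
            morphological_reconstruction(mask, mask), mask)

    def test_two_components_only_seeded_kept(self):
        mask = np.zeros((7, 7), bool)
        mask[1:3, 1:3] = True   # component A
        mask[4:6, 4:6] = True   # component B
        marker = np.zeros((7, 7), bool)
        marker[1, 1] = True
        out = morphological_reconstruction(marker, mask)
        assert out[1:3, 1:3].all() and not out[4:6, 4:6].any()

    def test_matches_brute_force_fixpoint(self, rng):
        """Label-based reconstruction equals iterated geodesic dilation."""
        for _ in range(200):
            mask = rng.random((12, 12)) > 0.55
            marker = mask & (rng.random((12, 12)) > 0.7)
            np.testing.assert_array_equal(
                morphological_reconstruction(marker, mask),
                brute_reconstruction(marker, mask))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            morphological_reconstruction(np.zeros((3, 3), bool),
                                         np.zeros((4, 4), bool))


class TestBinarizeVessels:
    def test_area_rule_at_seventy_pixels(self):
        fov = np.ones((20, 40), bool)
        r = np.zeros((20, 40))
        r[2:9, 1:11] = 1.0     # 70-px block -> kept
        r[12:15, 1:24] = 1.0   # 69-px block -> removed
        t = ThresholdPair(t_low=0.4, t_high=0.8)
        seg = binarize_vessels(r, fov, t, min_area=70)
        assert seg.binary[2:9, 1:11].all()
        assert not seg.binary[12:15, 1:24].any()
        assert seg.n_components_removed == 1

    def test_all_below_t_low_empty(self):
        fov = np.ones((10, 10), bool)
        seg = binarize_vessels(np.full((10, 10), 0.1), fov,
                               ThresholdPair(t_low=0.3, t_high=0.6))
        assert not seg.binary.any()

    def test_plateau_hysteresis(self):
        """A mid plateau survives only when connected to a marker plateau."""
        r = np.full((20, 20), 0.1)
        r[2:6, 2:6] = 0.9       # marker plateau
        r[6:10, 2:6] = 0.5      # mid plateau touching the marker
        r[14:18, 14:18] = 0.5   # isolated mid plateau
        fov = np.ones((20, 20), bool)
        seg = binarize_vessels(r, fov, ThresholdPair(t_low=0.4, t_high=0.8),
                               min_area=1)
        assert seg.binary[2:10, 2:6].all()
        assert not seg.binary[14:18, 14:18].any()

    def test_matches_brute_force_pipeline(self, rng):
        """Hysteresis + area filter equals the brute-force reconstruction
        and flood-fill area filter on random responses."""
        fov = np.ones((14, 14), bool)
        t = ThresholdPair(t_low=0.4, t_high=0.7)
        for _ in range(200):
            r = rng.random((14, 14))
            seg = binarize_vessels(r, fov, t, min_area=4)
            expected = brute_area_filter(
                brute_reconstruction(r >= 0.7, r >= 0.4), 4)
            np.testing.assert_array_equal(seg.binary, expected)

    def test_monotone_in_t_high_and_min_area(self, rng):
        fov = np.ones((24, 24), bool)
        r = rng.random((24, 24))
        base = binarize_vessels(r, fov, ThresholdPair(0.3, 0.5), min_area=3)
        stricter = binarize_vessels(r, fov, ThresholdPair(0.3, 0.7), min_area=3)
        bigger = binarize_vessels(r, fov, ThresholdPair(0.3, 0.5), min_area=10)
        assert not (stricter.binary & ~base.binary).any()
        assert not (bigger.binary & ~base.binary).any()

    def test_output_subset_of_mask_and_fov(self, rng):
        yy, xx = np.mgrid[0:30, 0:30]
        fov = np.hypot(yy - 15, xx - 15) <= 12
        r = rng.random((30, 30))
        t = ThresholdPair(0.5, 0.8)
        seg = binarize_vessels(r, fov, t, min_area=2)
        assert not (seg.binary & ~fov).any()
        assert not (seg.binary & ~((r >= 0.5) & fov)).any()

    def test_survivors_reach_min_area_and_marker(self, rng):
        from scipy import ndimage
        fov = np.ones((25, 25), bool)
        r = rng.random((25, 25))
        seg = binarize_vessels(r, fov, ThresholdPair(0.45, 0.75), min_area=5)
        labels, n = ndimage.label(seg.binary, structure=np.ones((3, 3)))
        marker = (r >= 0.75) & fov
        for k in range(1, n + 1):
            comp = labels == k
            assert comp.sum() >= 5
            assert (comp & marker).any()
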