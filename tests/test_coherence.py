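import numpy as np
import pytest

from retseg import (DiffusionParams, RidgeBankConfig, coherence_diffusion,
                    entropy_stopping, gaussian_2d, gaussian_second_derivative,
                    max_ridge_response, scale_normalization_case,
                    second_derivative_kernel, spatial_entropy)
from retseg.exceptions import ParameterError

from conftest import make_bar


class TestGaussian2D:
    def test_origin_value(self):
        assert gaussian_2d(0, 0, 1, 1) == pytest.approx(1 / (2 * np.pi))

    def test_separability(self, rng):
        u = rng.uniform(-5, 5, 50)
        v = rng.uniform(-5, 5, 50)
        su, sv = 2.0, 3.0
        g1 = lambda t, s: np.exp(-t ** 2 / (2 * s * s)) / (np.sqrt(2 * np.pi) * s)
        np.testing.assert_allclose(gaussian_2d(u, v, su, sv),
                                   g1(u, su) * g1(v, sv), rtol=1e-12)

    def test_symmetry(self, rng):
        u, v = rng.uniform(-4, 4, 20), rng.uniform(-4, 4, 20)
        np.testing.assert_allclose(gaussian_2d(u, v, 2, 1.5),
                                   gaussian_2d(-u, v, 2, 1.5))
        np.testing.assert_allclose(gaussian_2d(u, v, 2, 1.5),
                                   gaussian_2d(u, -v, 2, 1.5))

    def test_invalid_sigma(self):
        with pytest.raises(ParameterError):
            gaussian_2d(0, 0, 0, 1)


class TestSecondDerivative:
    def test_origin_closed_form(self):
        assert gaussian_second_derivative(0, 0, 1, 1) == pytest.approx(-1 / (2 * np.pi))
        su, sv = 2.5, 4.0
        assert gaussian_second_derivative(0, 0, su, sv) == pytest.approx(
            -1 / (2 * np.pi * su ** 3 * sv))

    def test_kernel_theta0_matches_axis_aligned_sampling(self):
        su, sv = 2.0, 3.0
        k = second_derivative_kernel(su, sv, 0.0)
        half = k.shape[0] // 2
        coords = np.arange(-half, half + 1, dtype=float)
        direct = gaussian_second_derivative(coords[None, :], coords[:, None], su, sv)
        np.testing.assert_allclose(k, direct - direct.mean(), atol=1e-15)

    def test_kernel_theta90_is_transpose(self):
        k0 = second_derivative_kernel(2.0, 3.0, 0.0)
        k90 = second_derivative_kernel(2.0, 3.0, 90.0)
        np.testing.assert_allclose(k90, k0.T, atol=1e-12)

    def test_kernel_sums_to_zero(self):
        for su, sv, th in [(2, 4, 0), (4, 5, 30), (10, 4, 75), (17.5, 5, 120)]:
            k = second_derivative_kernel(su, sv, th)
            assert abs(k.sum()) < 1e-3 * np.abs(k).sum()

    @pytest.mark.parametrize("sigma", [2.0, 3.0, 5.0])
    def test_matches_finite_difference_of_gaussian(self, sigma):
        """Centered second difference of finely sampled Gaussian grids
        reproduces the analytic kernel to <1% relative error."""
        h = 0.25
        half = int(np.ceil(3 * sigma / h))
        coords = np.arange(-half, half + 1) * h
        g = gaussian_2d(coords[None, :], coords[:, None], sigma, sigma)
        fd = (np.roll(g, -1, axis=1) - 2 * g + np.roll(g, 1, axis=1)) / h ** 2
        analytic = gaussian_second_derivative(coords[None, :], coords[:, None],
                                              sigma, sigma)
        interior = (slice(4, -4), slice(4, -4))
        err = np.abs(fd[interior] - analytic[interior]).max()
        assert err < 0.01 * np.abs(analytic[interior]).max()


class TestScaleNormalizationCase:
    @pytest.mark.parametrize("case,expected", [
        (1, (0.5, 0.5)), (2, (1.0, 0.5)), (3, (1.5, 0.5)), (4, (1.0, 0.5))])
    def test_case_table(self, case, expected):
        assert scale_normalization_case(case) == expected

    def test_unknown_case(self):
        with pytest.raises(ParameterError):
            scale_normalization_case(5)


class TestMaxRidgeResponse:
    def test_constant_image_zero_response(self):
        fov = np.ones((64, 64), bool)
        rr = max_ridge_response(np.full((64, 64), 0.5), fov)
        np.testing.assert_allclose(rr.response, 0.0, atol=1e-9)

    @pytest.mark.parametrize("angle", [0, 30, 45, 120])
    def test_dark_bar_orientation_recovered(self, angle):
        img, center = make_bar(160, 160, angle)
        rr = max_ridge_response(img, np.ones_like(img, bool))
        match = np.mean(rr.best_orientation[center] == angle)
        assert match >= 0.90

    def test_rotation_shifts_orientation_by_one_step(self):
        """A bar rotated by one orientation step moves the centerline argmax
        orientation by exactly that step on most pixels."""
        step = RidgeBankConfig().orientation_step
        img0, c0 = make_bar(160, 160, 45)
        img1, c1 = make_bar(160, 160, 45 + step)
        r0 = max_ridge_response(img0, np.ones_like(img0, bool))
        r1 = max_ridge_response(img1, np.ones_like(img1, bool))
        assert np.mean(r0.best_orientation[c0] == 45) >= 0.85
        assert np.mean((r1.best_orientation[c1] - 45) % 180 == step) >= 0.85

    def test_wider_bar_selects_larger_cross_section_scale(self):
        """The argmax cross-section scale sigma_u orders with ridge width."""
        yy, xx = np.mgrid[0:220, 0:220].astype(float)
        img = np.full((220, 220), 0.8)
        for col, s in ((60, 2.0), (160, 5.0)):
            img -= 0.5 * np.exp(-(xx - col) ** 2 / (2 * s * s))
        rr = max_ridge_response(np.clip(img, 0, 1), np.ones_like(img, bool))
        modal = []
        for col in (60, 160):
            sel = np.abs(xx - col) <= 0.5
            vals, counts = np.unique(rr.best_sigma_u[sel], return_counts=True)
            modal.append(vals[np.argmax(counts)])
        assert modal[0] < modal[1]

    def test_thin_vessel_response_favored_by_case2_over_case3(self, small_phantom):
        """Lower alpha weights thin vessels relative to wide ones: the
        thin-to-wide centerline response ratio is higher under case 2 than
        case 3 (rescale-invariant form of the sensitivity-vs-alpha
        direction)."""
        from scipy import ndimage
        image, truth, fov, cl = small_phantom
        inner = ndimage.distance_transform_edt(truth)
        widths = inner[cl[:, 0], cl[:, 1]]
        thin, wide = cl[widths <= 1.0], cl[widths >= 3.0]
        f = 1.0 - image.green
        ratio = {}
        for case in (2, 3):
            a, b = scale_normalization_case(case)
            r = max_ridge_response(f, fov, RidgeBankConfig(alpha=a, beta=b)).response
            ratio[case] = (r[thin[:, 0], thin[:, 1]].mean()
                           / r[wide[:, 0], wide[:, 1]].mean())
        assert ratio[2] > ratio[3]

    def test_argmax_fields_populated_where_positive(self):
        img, _ = make_bar(80, 80, 30)
        rr = max_ridge_response(img, np.ones_like(img, bool))
        positive = rr.response > 0
        assert not np.any(np.isnan(rr.best_orientation[positive]))
        assert not np.any(np.isnan(rr.best_sigma_u[positive]))


class TestEntropyStopping:
    @pytest.mark.parametrize("trace,tol,expected", [
        ([2.0, 2.0, 2.0], 1e-4, True),
        ([2.0, 1.5, 1.0], 1e-4, False),
        ([2.0, 1.99, 1.9899, 1.98988], 1e-3, True),
        ([2.0, 2.0], 1e-4, False),
    ])
    def test_rule(self, trace, tol, expected):
        assert entropy_stopping(trace, tol) is expected

    def test_empty_trace_rejected(self):
        with pytest.raises(ParameterError):
            entropy_stopping([], 1e-3)


class TestCoherenceDiffusion:
    def test_zero_image_unchanged_early_stop(self):
        z = np.zeros((40, 40))
        out, iters, trace = coherence_diffusion(z, DiffusionParams())
        np.testing.assert_allclose(out, 0.0)
        assert iters == 2  # first possible entropy-stability check
        assert len(trace) == 3

    def test_noisy_ridge_centerline_variance_decreases(self, rng):
        img, center = make_bar(96, 96, 0, halfwidth=1.5)
        img = np.clip(img + 0.05 * rng.standard_normal(img.shape), 0, 1)
        p = DiffusionParams(max_iterations=20, entropy_tolerance=1e-12,
                            coherence_gain=1e-7)
        out, iters, _ = coherence_diffusion(img, p)
        assert out[center].var() < img[center].var()

    def test_iterations_bounded(self, rng):
        img = rng.random((32, 32))
        p = DiffusionParams(max_iterations=5, entropy_tolerance=1e-12)
        _, iters, trace = coherence_diffusion(img, p)
        assert iters <= 5
        assert len(trace) == iters + 1

    def test_interior_mean_conserved(self, rng):
        from scipy import ndimage
        img = ndimage.gaussian_filter(rng.random((100, 100)), 3)
        img = (img - img.min()) / (img.max() - img.min())
        p = DiffusionParams(max_iterations=20, entropy_tolerance=1e-12)
        out, _, _ = coherence_diffusion(img, p)
        inner = (slice(2, -2), slice(2, -2))
        drift = abs(out[inner].mean() - img[inner].mean()) / img[inner].mean()
        assert drift < 1e-3  # 0.5% per 100 iterations

    def test_entropy_of_uniform_histogram(self):
        img = np.linspace(0, 1, 64 * 64).reshape(64, 64)
        assert spatial_entropy(img, bins=64) == pytest.approx(np.log(64), abs=1e-6)

    def test_invalid_time_step(self):
        with pytest.raises(ParameterError):
            DiffusionParams(time_step=0.3)
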