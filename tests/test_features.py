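import numpy as np
import pytest

from mvnquant.features import (
    FeatureConfig,
    compute_feature_stack,
    difference_of_gaussians,
    hessian_eigenimages,
    membrane_kernels,
    membrane_projections,
    scale_set,
)
from mvnquant.imaging import CalibratedImage, ValidationError


def img(a, role="phase", px=1.0):
    return CalibratedImage(np.asarray(a, dtype=float), role, px)


class TestScaleSet:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (1.0, 16.0, [1.0, 2.0, 4.0, 8.0, 16.0]),
            (2.0, 2.0, [2.0]),
            (1.0, 10.0, [1.0, 2.0, 4.0, 8.0]),
        ],
    )
    def test_powers_of_two_ladder(self, lo, hi, expected):
        assert scale_set(FeatureConfig(sigma_min=lo, sigma_max=hi)) == expected

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValidationError):
            FeatureConfig(sigma_min=4.0, sigma_max=1.0)


class TestDifferenceOfGaussians:
    def test_identical_sigmas_cancel(self, rng):
        a = rng.random((32, 32)) * 100
        assert np.allclose(difference_of_gaussians(img(a), 2.0, 2.0), 0.0)

    def test_constant_image_is_flat(self):
        out = difference_of_gaussians(img(np.full((32, 32), 7.0)), 1.0, 4.0)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_impulse_matches_analytic_kernel_difference(self):
        # independent oracle: separable sampled-Gaussian kernels truncated at
        # 4 sigma, exactly the definition the filter implements
        def sampled_gaussian_image(sigma, size, center):
            r = int(4.0 * sigma + 0.5)
            x = np.arange(-r, r + 1)
            k = np.exp(-0.5 * (x / sigma) ** 2)
            k /= k.sum()
            out = np.zeros(size)
            plane = np.outer(k, k)
            out[center - r: center + r + 1, center - r: center + r + 1] = plane
            return out

        n, c = 129, 64
        impulse = np.zeros((n, n))
        impulse[c, c] = 1.0
        got = difference_of_gaussians(img(impulse), 1.5, 4.0)
        want = sampled_gaussian_image(1.5, (n, n), c) - sampled_gaussian_image(4.0, (n, n), c)
        assert np.allclose(got, want, atol=1e-6)

    def test_orientation_convention_min_sigma_minus_max(self, rng):
        # the output is fixed to blur(min) - blur(max) regardless of argument order
        a = rng.random((32, 32))
        assert np.array_equal(
            difference_of_gaussians(img(a), 1.0, 4.0),
            difference_of_gaussians(img(a), 4.0, 1.0),
        )


class TestHessian:
    def test_constant_image_zero(self):
        # kernel truncation leaves ~1e-4 residual curvature on a constant
        hi, lo = hessian_eigenimages(img(np.full((32, 32), 3.0)), 2.0)
        assert np.allclose(hi, 0.0, atol=1e-3)
        assert np.allclose(lo, 0.0, atol=1e-3)

    def test_quadratic_ramp_curvature(self):
        # f(x) = x^2 has Hessian diag(2, 0): eigenvalues 2 and 0 in the
        # interior; kernel truncation leaves a residual proportional to x^2,
        # so the ramp is centred and the tolerance set by that residual
        x = np.arange(64, dtype=float) - 31.5
        a = np.tile(x**2, (64, 1))
        hi, lo = hessian_eigenimages(img(a), 2.0)
        interior = (slice(16, 48), slice(16, 48))
        assert np.allclose(hi[interior], 2.0, atol=0.1)
        assert np.allclose(lo[interior], 0.0, atol=0.1)

    def test_bright_ridge_has_negative_smallest_eigenvalue(self):
        a = np.zeros((41, 41))
        a[20, :] = 100.0
        _, lo = hessian_eigenimages(img(a), 2.0)
        assert lo[20, 20] < -1.0
        assert lo[20, 20] == np.min(lo[:, 20])


class TestMembraneProjections:
    def test_each_kernel_has_patch_size_pixels(self):
        config = FeatureConfig()  # thickness 1, patch 19, 30 rotations
        kernels = membrane_kernels(config)
        assert kernels.shape == (30, 19, 19)
        assert all(int((k > 0).sum()) == 19 for k in kernels)

    def test_constant_image_reductions(self):
        config = FeatureConfig(n_membrane_rotations=12)
        out = membrane_projections(img(np.full((40, 40), 5.0)), config)
        # sum/mean/median/max/min constant, std zero
        for plane in (out[0], out[1], out[3], out[4], out[5]):
            assert np.allclose(plane, plane.flat[0])
        assert np.allclose(out[2], 0.0, atol=1e-9)

    def test_bright_line_maximizes_max_projection(self):
        from scipy import signal

        config = FeatureConfig(n_membrane_rotations=12)
        a = np.zeros((41, 41))
        a[20, :] = 10.0  # horizontal line of width 1
        out = membrane_projections(img(a), config)
        # direct-convolution oracle with the horizontally oriented kernel
        kernels = membrane_kernels(config)
        horizontal = kernels[0]  # angle 0 -> line along columns
        padded = np.pad(a, 9, mode="reflect")
        oracle = signal.convolve2d(padded, horizontal[::-1, ::-1], mode="valid")
        assert np.allclose(out[4][20, 15:25], oracle[20, 15:25])
        assert out[4][20, 20] == pytest.approx(out[4].max())


class TestFeatureStack:
    def test_plane_count_single_family(self, rng):
        a = img(rng.random((24, 24)))
        config = FeatureConfig(families=("gaussian_blur",))
        stack = compute_feature_stack([a], config)
        assert stack.n_features == 6  # raw + 5 blur scales
        assert len(set(stack.names)) == 6

    def test_two_channels_double_the_bank(self, rng):
        config = FeatureConfig(families=("gaussian_blur", "sobel"))
        one = compute_feature_stack([img(rng.random((24, 24)))], config)
        two = compute_feature_stack(
            [img(rng.random((24, 24)), "phase"), img(rng.random((24, 24)), "gfp")],
            config,
        )
        assert two.n_features == 2 * one.n_features

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValidationError):
            compute_feature_stack(
                [img(rng.random((24, 24))), img(rng.random((24, 25)))],
            )

    def test_deterministic(self, rng):
        a = img(rng.random((24, 24)))
        config = FeatureConfig(sigma_max=4.0, n_membrane_rotations=8,
                               membrane_patch_size=9)
        s1 = compute_feature_stack([a], config)
        s2 = compute_feature_stack([a], config)
        assert np.array_equal(s1.features, s2.features)

    def test_translation_equivariance_in_the_interior(self, rng):
        config = FeatureConfig(sigma_max=2.0, n_membrane_rotations=8,
                               membrane_patch_size=9)
        base = rng.random((64, 64))
        dy, dx = 3, 5
        shifted = np.roll(np.roll(base, dy, axis=0), dx, axis=1)
        s0 = compute_feature_stack([img(base)], config).features
        s1 = compute_feature_stack([img(shifted)], config).features
        pad = 20  # beyond any filter support
        assert np.allclose(
            s0[:, pad:-pad - dy, pad:-pad - dx],
            s1[:, pad + dy:-pad, pad + dx:-pad],
            atol=1e-10,
        )
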