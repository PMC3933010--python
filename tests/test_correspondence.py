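"""Axis reordering, circularity relaxation, rotation smoothing and
resampling to a common slice count."""

import numpy as np
import pytest

from ellipstack.correspondence import (
    interpolate_stack,
    relax_circular,
    reorder_axes,
    resample_stack,
    smooth_rotation,
    unwrap_angles,
)
from ellipstack.errors import InvalidParameterError
from ellipstack.geometry import EllipseStack, ellipse_boundary, project_points_to_ellipse
from conftest import smooth_stack


def boundary_set_distance(p_before, p_after) -> float:
    """Max distance from sampled points of one ellipse to the other's
    boundary — zero iff the two parameter sets describe the same ellipse."""
    d1 = project_points_to_ellipse(p_after, ellipse_boundary(p_before, 128))[1].max()
    d2 = project_points_to_ellipse(p_before, ellipse_boundary(p_after, 128))[1].max()
    return max(float(d1), float(d2))


def random_stack(rng, L=7) -> EllipseStack:
    theta = rng.uniform(-10, 10, (L, 2))
    alpha = rng.uniform(5, 25, (L, 2))
    phi = rng.uniform(-np.pi / 2, np.pi / 2, L)
    return EllipseStack.from_arrays(3.3 * np.arange(L), theta, alpha, phi)


class TestReorder:
    def test_identical_slices_unchanged(self):
        s = smooth_stack()
        out = reorder_axes(s)
        assert np.allclose(out.phi, s.phi)
        assert np.allclose(out.alpha, s.alpha)

    @pytest.mark.parametrize(
        "alpha1, phi1",
        [((1.0, 2.0), 0.1), ((1.0, 2.0), -1.5), ((3.0, 1.5), 1.4)],
    )
    def test_neighbor_takes_representation_nearest_basis(self, alpha1, phi1):
        # the four equivalent representations of the neighbor slice are
        # {(a1,a2,phi), (a1,a2,phi+pi), (a2,a1,phi+/-pi/2)}; the one whose
        # angle is nearest the basis angle must be chosen (brute force)
        z = [0.0, 1.0]
        theta = np.zeros((2, 2))
        alpha = np.array([[2.0, 1.0], alpha1])
        phi = np.array([0.05, phi1])
        out = reorder_axes(EllipseStack.from_arrays(z, theta, alpha, phi))
        # center slice of a 2-stack is index 0 (1-based ceil(2/2) = 1)
        assert np.allclose(out.alpha[0], [2, 1]) and out.phi[0] == 0.05
        # brute-force the best representation
        cands = []
        a1, a2 = alpha1
        for a, p in [
            ((a1, a2), phi1),
            ((a1, a2), phi1 + np.pi),
            ((a2, a1), phi1 + np.pi / 2),
            ((a2, a1), phi1 - np.pi / 2),
        ]:
            p_adj = p + 2 * np.pi * np.round((0.05 - p) / (2 * np.pi))
            cands.append((abs(p_adj - 0.05), a, p_adj))
        _, best_a, best_p = min(cands)
        assert np.allclose(out.alpha[1], best_a)
        assert out.phi[1] == pytest.approx(best_p, abs=1e-12)
        # boundary unchanged
        s_in = EllipseStack.from_arrays(z, theta, alpha, phi)
        for before, after in zip(s_in.params, out.params):
            assert boundary_set_distance(before, after) < 1e-9

    def test_boundaries_never_change(self, rng):
        for _ in range(10):
            s = random_stack(rng)
            out = reorder_axes(s)
            for before, after in zip(s.params, out.params):
                assert boundary_set_distance(before, after) < 1e-9

    def test_adjacent_angle_gap_at_most_quarter_pi(self, rng):
        # the four representations are spaced pi/2 apart, so the chosen one
        # is always within pi/4 of the processed neighbor
        for _ in range(10):
            out = reorder_axes(random_stack(rng))
            d = np.abs(np.diff(unwrap_angles(out.phi)))
            assert np.all(d <= np.pi / 4 + 1e-9)

    def test_center_slice_within_pi_of_all(self, rng):
        out = reorder_axes(random_stack(rng, L=9))
        mid = (len(out) + 1) // 2 - 1
        phi_u = unwrap_angles(out.phi)
        assert np.max(np.abs(phi_u - phi_u[mid])) <= np.pi

    def test_idempotent(self, rng):
        s = reorder_axes(random_stack(rng))
        out = reorder_axes(s)
        assert np.allclose(out.phi, s.phi, atol=1e-12)
        assert np.allclose(out.alpha, s.alpha, atol=1e-12)


class TestRelaxCircular:
    def test_perfect_circle_takes_neighbor_mean(self):
        z = [0, 1, 2]
        theta = np.zeros((3, 2))
        alpha = np.array([[2.0, 1.0], [5.0, 5.0], [2.0, 1.0]])
        phi = np.array([0.3, 0.9, 0.3])
        out = relax_circular(EllipseStack.from_arrays(z, theta, alpha, phi), 0.95)
        assert out.phi[1] == pytest.approx(0.3, abs=1e-12)

    def test_below_threshold_unchanged(self):
        s = smooth_stack()  # aspect 0.7 everywhere
        out = relax_circular(s, 0.95)
        assert np.allclose(out.phi, s.phi)

    def test_halfway_blend_hand_computed(self):
        # c = 0.975, threshold 0.95 -> w = 0.5; phi 0.8, neighbor mean 0.2
        z = [0, 1, 2]
        theta = np.zeros((3, 2))
        alpha = np.array([[10.0, 5.0], [10.0, 9.75], [10.0, 5.0]])
        phi = np.array([0.1, 0.8, 0.3])
        out = relax_circular(EllipseStack.from_arrays(z, theta, alpha, phi), 0.95)
        assert out.phi[1] == pytest.approx(0.5, abs=1e-12)

    def test_single_slice_returned_unchanged(self):
        s = EllipseStack.from_arrays([0.0], [[0, 0]], [[3, 3]], [0.2])
        out = relax_circular(s, 0.95)
        assert out.phi[0] == 0.2


class TestSmoothRotation:
    def test_constant_sequence_unchanged(self):
        s = smooth_stack(phi0=0.4)
        out = smooth_rotation(s, 3)
        assert np.allclose(out.phi, s.phi, atol=1e-12)

    def test_window3_hand_computed_with_clipped_ends(self):
        z = [0, 1, 2]
        s = EllipseStack.from_arrays(
            z, np.zeros((3, 2)), np.full((3, 2), 5.0), [0.0, 0.3, 0.0]
        )
        out = smooth_rotation(s, 3)
        assert np.allclose(out.phi, [0.15, 0.1, 0.15], atol=1e-12)

    def test_total_variation_never_increases(self, rng):
        for _ in range(100):
            L = int(rng.integers(3, 12))
            phi = rng.uniform(-1.2, 1.2, L)
            s = EllipseStack.from_arrays(
                np.arange(L), np.zeros((L, 2)), np.full((L, 2), 5.0), phi
            )
            out = smooth_rotation(s, 3)
            tv_in = np.abs(np.diff(unwrap_angles(phi))).sum()
            tv_out = np.abs(np.diff(unwrap_angles(out.phi))).sum()
            assert tv_out <= tv_in + 1e-9

    def test_theta_alpha_untouched(self, rng):
        s = random_stack(rng)
        out = smooth_rotation(s, 3)
        assert np.array_equal(out.theta, s.theta)
        assert np.array_equal(out.alpha, s.alpha)

    def test_even_window_rejected(self):
        with pytest.raises(InvalidParameterError):
            smooth_rotation(smooth_stack(), 4)


class TestResample:
    def test_same_length_reproduces_input(self):
        s = smooth_stack(L=9)
        out = resample_stack(s, 9)
        assert np.allclose(out.theta, s.theta, atol=1e-10)
        assert np.allclose(out.alpha, s.alpha, atol=1e-10)
        assert np.allclose(out.phi, s.phi, atol=1e-10)
        assert np.allclose(out.z, s.z, atol=1e-10)

    def test_linear_parameters_stay_linear(self):
        L = 6
        t = np.linspace(0, 1, L)
        theta = np.column_stack([1 + 2 * t, -3 + t])
        alpha = np.column_stack([10 + 5 * t, 8 + 2 * t])
        phi = 0.1 + 0.2 * t
        s = EllipseStack.from_arrays(10 * t, theta, alpha, phi)
        out = resample_stack(s, 11)
        tt = np.linspace(0, 1, 11)
        assert np.allclose(out.theta[:, 0], 1 + 2 * tt, atol=1e-10)
        assert np.allclose(out.alpha[:, 1], 8 + 2 * tt, atol=1e-10)
        assert np.allclose(out.phi, 0.1 + 0.2 * tt, atol=1e-10)

    def test_cubic_polynomial_reproduced(self):
        # parameters that are exact cubics in t are reproduced exactly by
        # cubic spline interpolation through 11 knots
        t = np.linspace(0, 1, 11)

        def cubic(c):
            return c[0] + c[1] * t + c[2] * t**2 + c[3] * t**3

        theta = np.column_stack([cubic([1, 2, -1, 0.5]), cubic([0, -1, 2, -0.3])])
        alpha = np.column_stack([cubic([15, 3, -2, 1]), cubic([10, 2, -1, 0.5])])
        phi = cubic([0.1, 0.3, -0.2, 0.1])
        s = EllipseStack.from_arrays(33 * t, theta, alpha, phi)
        out = resample_stack(s, 21)
        tt = np.linspace(0, 1, 21)

        def cubic_at(c, x):
            return c[0] + c[1] * x + c[2] * x**2 + c[3] * x**3

        assert np.max(np.abs(out.theta[:, 0] - cubic_at([1, 2, -1, 0.5], tt))) < 1e-8
        assert np.max(np.abs(out.alpha[:, 0] - cubic_at([15, 3, -2, 1], tt))) < 1e-8
        assert np.max(np.abs(out.phi - cubic_at([0.1, 0.3, -0.2, 0.1], tt))) < 1e-8

    def test_translation_commutes(self, rng):
        s = random_stack(rng, L=8)
        shift = np.array([5.0, -7.0])
        s2 = EllipseStack.from_arrays(s.z, s.theta + shift, s.alpha, s.phi)
        a = resample_stack(s, 13)
        b = resample_stack(s2, 13)
        assert np.allclose(b.theta, a.theta + shift, atol=1e-10)

    def test_small_L_rejected(self):
        with pytest.raises(InvalidParameterError):
            resample_stack(smooth_stack(), 2)

    def test_two_slice_stack_degrades_to_linear(self):
        s = EllipseStack.from_arrays(
            [0.0, 10.0], [[0, 0], [2, 2]], [[4, 3], [6, 5]], [0.0, 0.2]
        )
        out = resample_stack(s, 5)
        assert np.allclose(out.theta[:, 0], np.linspace(0, 2, 5), atol=1e-12)

    def test_interpolate_at_arbitrary_positions(self):
        s = smooth_stack(L=9)
        out = interpolate_stack(s, [0.0, 0.5, 1.0])
        assert np.allclose(out.theta[0], s.theta[0], atol=1e-10)
        assert np.allclose(out.theta[-1], s.theta[-1], atol=1e-10)
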