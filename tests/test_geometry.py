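"""Perceived-space geometry: Hill modulation, metric changes, ellipsoid
surface, ellipse fitting and prism-area inference."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from percspace import (DegenerateMetricError, EllipsoidParams, FitFailureError,
                       HillParams, InvalidInputError, MetricTensor,
                       PerceptualModulationParams, delta_metric,
                       ellipsoid_metric, fit_rotated_ellipse,
                       gaussian_curvature_ellipsoid, metric_from_prism_area,
                       modulation_index, perceived_metric)
from percspace.synthetic import synth_rod_positions

PSI_HILL = HillParams(14.8, 1.39)


class TestModulationIndex:
    def test_half_effect_and_limits(self):
        assert modulation_index(1.39, PSI_HILL) == pytest.approx(0.5)
        assert modulation_index(0.0, PSI_HILL) == 0.0
        # C = 2k with the psilocybin fit: 1/(1 + 0.5^14.8)
        assert modulation_index(2.78, PSI_HILL) == pytest.approx(1 / (1 + 0.5**14.8), rel=1e-12)

    def test_rejects_negative_concentration(self):
        with pytest.raises(InvalidInputError):
            modulation_index(-0.1, PSI_HILL)

    @settings(derandomize=True, max_examples=50)
    @given(n=st.floats(0.2, 80.0), k=st.floats(0.01, 10.0),
           c1=st.floats(1e-6, 1e3), factor=st.floats(1.001, 10.0))
    def test_strictly_increasing_with_unit_range(self, n, k, c1, factor):
        hill = HillParams(n, k)
        m1 = modulation_index(c1, hill)
        m2 = modulation_index(c1 * factor, hill)
        assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0
        assert m2 >= m1

    def test_saturation_limits(self):
        assert modulation_index(1e12, HillParams(2.0, 1.0)) > 1 - 1e-12
        assert modulation_index(1e-12, HillParams(2.0, 1.0)) < 1e-12


class TestDeltaMetric:
    def test_no_drug_gives_zero_change(self):
        d = delta_metric(0.0, PerceptualModulationParams())
        assert np.all(d.components == 0.0)

    def test_peak_deviation_equals_g_max_at_fixation_point(self):
        d = delta_metric(1.0, PerceptualModulationParams(1, 1.0, (1.0, 1.0, 1.0)),
                         r=1.0, theta=0.0)
        assert np.allclose(d.components, np.eye(3))

    def test_hypoactivation_with_weber_scaling(self):
        mod = PerceptualModulationParams(-1, 2.0, (1.0, 1.0, 1.0))
        d = delta_metric(0.5, mod, r=1.0, theta=0.0)
        assert np.allclose(np.diag(d.components), [-0.25, -0.25, -0.25])
        assert np.allclose(d.components - np.diag(np.diag(d.components)), 0.0)

    def test_linear_in_modulation_and_odd_in_arousal(self):
        up = PerceptualModulationParams(1, 1.5, (0.8, 1.2, 0.9))
        down = PerceptualModulationParams(-1, 1.5, (0.8, 1.2, 0.9))
        d1 = delta_metric(0.3, up, r=0.7, theta=0.4)
        d2 = delta_metric(0.6, up, r=0.7, theta=0.4)
        d3 = delta_metric(0.3, down, r=0.7, theta=0.4)
        assert np.allclose(2 * d1.components, d2.components)
        assert np.allclose(d3.components, -d1.components)

    def test_modulation_out_of_range_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_metric(1.2, PerceptualModulationParams())


class TestPerceivedMetric:
    def test_additive_combination(self):
        eye = MetricTensor(np.eye(3), ("r", "theta", "phi"))
        zero = MetricTensor(np.zeros((3, 3)), ("r", "theta", "phi"))
        bump = MetricTensor(np.diag([0.2, 0.2, 0.2]), ("r", "theta", "phi"))
        assert np.allclose(perceived_metric(eye, zero).components, np.eye(3))
        assert np.allclose(perceived_metric(eye, bump).components, np.diag([1.2] * 3))

    def test_negative_diagonal_is_degenerate(self):
        eye = MetricTensor(np.eye(3), ("r", "theta", "phi"))
        drop = MetricTensor(np.diag([-1.5, 0.0, 0.0]), ("r", "theta", "phi"))
        with pytest.raises(DegenerateMetricError):
            perceived_metric(eye, drop)


def _fd_metric(a, b, alpha, beta, h=1e-6):
    """Finite-difference first fundamental form (J^T J) oracle."""
    def point(al, be):
        return np.array([a * np.cos(al) * np.cos(be),
                         b * np.cos(al) * np.sin(be),
                         a * np.sin(al)])
    ra = (point(alpha + h, beta) - point(alpha - h, beta)) / (2 * h)
    rb = (point(alpha, beta + h) - point(alpha, beta - h)) / (2 * h)
    J = np.column_stack([ra, rb])
    return J.T @ J


class TestEllipsoidSurface:
    def test_sphere_limit_collapses_to_closed_form(self):
        R = 2.5
        for alpha, beta in [(0.0, 0.0), (0.4, 1.1), (-0.9, 2.7), (1.2, -0.3)]:
            g = ellipsoid_metric(EllipsoidParams(R, R), alpha, beta)
            expected = np.diag([R**2, R**2 * np.cos(alpha) ** 2])
            assert np.allclose(g.components, expected, atol=1e-12)

    def test_axis_point_value(self):
        g = ellipsoid_metric(EllipsoidParams(2.0, 1.0), 0.0, np.pi / 2)
        assert np.allclose(g.components, [[4.0, 0.0], [0.0, 4.0]], atol=1e-12)

    def test_matches_finite_difference_jacobian_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a, b = rng.uniform(0.5, 3.0, 2)
            alpha = rng.uniform(-1.2, 1.2)
            beta = rng.uniform(0.0, 2 * np.pi)
            g = ellipsoid_metric(EllipsoidParams(a, b), alpha, beta).components
            assert np.allclose(g, _fd_metric(a, b, alpha, beta), atol=1e-8)
        # off-diagonal symmetry holds exactly by construction
        g = ellipsoid_metric(EllipsoidParams(1.7, 0.6), 0.5, 0.8).components
        assert g[0, 1] == g[1, 0]

    def test_sphere_curvature_is_inverse_square_radius(self):
        for R in (0.5, 1.0, 3.0):
            for alpha, beta in [(0.0, 0.0), (0.7, 2.0), (-0.5, 4.0)]:
                K = gaussian_curvature_ellipsoid(EllipsoidParams(R, R), alpha, beta)
                assert K == pytest.approx(1 / R**2, abs=1e-10)

    def test_curvature_matches_finite_difference_second_form(self):
        # independent oracle: numerically differentiate the embedding twice
        a, b, alpha, beta = 2.0, 1.0, 0.0, 0.0
        h = 1e-5

        def point(al, be):
            return np.array([a * np.cos(al) * np.cos(be),
                             b * np.cos(al) * np.sin(be),
                             a * np.sin(al)])

        ra = (point(alpha + h, beta) - point(alpha - h, beta)) / (2 * h)
        rb = (point(alpha, beta + h) - point(alpha, beta - h)) / (2 * h)
        raa = (point(alpha + h, beta) - 2 * point(alpha, beta) + point(alpha - h, beta)) / h**2
        rbb = (point(alpha, beta + h) - 2 * point(alpha, beta) + point(alpha, beta - h)) / h**2
        rab = (point(alpha + h, beta + h) - point(alpha + h, beta - h)
               - point(alpha - h, beta + h) + point(alpha - h, beta - h)) / (4 * h**2)
        n = np.cross(ra, rb)
        n /= np.linalg.norm(n)
        E, F, G = ra @ ra, ra @ rb, rb @ rb
        L, M, N = raa @ n, rab @ n, rbb @ n
        K_fd = (L * N - M**2) / (E * G - F**2)
        K = gaussian_curvature_ellipsoid(EllipsoidParams(a, b), alpha, beta)
        assert K == pytest.approx(K_fd, abs=1e-6)

    def test_curvature_periodic_in_beta(self):
        ell = EllipsoidParams(2.0, 1.3)
        k1 = gaussian_curvature_ellipsoid(ell, 0.5, 0.9)
        k2 = gaussian_curvature_ellipsoid(ell, 0.5, 0.9 + 2 * np.pi)
        assert k1 == pytest.approx(k2, rel=1e-12)


class TestRotatedEllipseFit:
    def test_noiseless_recovery(self):
        pts = synth_rod_positions(EllipsoidParams(3.0, 1.0, 0.4), (0.0, 0.0), 12)
        fit, center = fit_rotated_ellipse(pts.to_numpy())
        assert fit.semi_axis_a == pytest.approx(3.0, rel=1e-6)
        assert fit.semi_axis_b == pytest.approx(1.0, rel=1e-6)
        assert fit.rotation_angle == pytest.approx(0.4, abs=1e-6)
        assert center == pytest.approx((0.0, 0.0), abs=1e-6)

    def test_noisy_recovery_within_two_percent(self):
        pts = synth_rod_positions(EllipsoidParams(3.0, 1.0, 0.4), (1.0, 2.0),
                                  24, noise_sd=0.01, seed=7)
        fit, _ = fit_rotated_ellipse(pts.to_numpy())
        assert fit.semi_axis_a == pytest.approx(3.0, rel=0.02)
        assert fit.semi_axis_b == pytest.approx(1.0, rel=0.02)
        assert fit.rotation_angle == pytest.approx(0.4, abs=0.02)

    def test_degenerate_inputs_fail_cleanly(self):
        with pytest.raises(InvalidInputError):
            fit_rotated_ellipse([(0, 0), (1, 1), (2, 2), (3, 3)])
        with pytest.raises(FitFailureError):
            fit_rotated_ellipse([(i, 2.0 * i) for i in range(6)])

    def test_axis_ordering_and_angle_range(self):
        # generator major axis along y: fitted angle must stay in (-pi/2, pi/2]
        pts = synth_rod_positions(EllipsoidParams(1.0, 2.5, 0.0), (0.0, 0.0), 16)
        fit, _ = fit_rotated_ellipse(pts.to_numpy())
        assert fit.semi_axis_a >= fit.semi_axis_b
        assert -np.pi / 2 < fit.rotation_angle <= np.pi / 2
        assert fit.semi_axis_a == pytest.approx(2.5, rel=1e-6)


class TestPrismAreaInference:
    @pytest.mark.parametrize("obs,expected", [(100.0, 1.0), (50.0, 2.0), (200.0, 0.5)])
    def test_equal_area_convention(self, obs, expected):
        assert metric_from_prism_area(100.0, obs) == pytest.approx(expected)

    def test_positive_areas_required(self):
        with pytest.raises(InvalidInputError):
            metric_from_prism_area(0.0, 1.0)
        with pytest.raises(InvalidInputError):
            metric_from_prism_area(1.0, -2.0)
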