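"""Steady-state IFP field against independent finite-difference oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.sparse import diags
from scipy.sparse.linalg import spsolve

import ittm
from ittm.pressure import central_ifp_fraction, ifp_profile


def fd_pressure_oracle(alpha, p_v, radius, n=10_000):
    """Solve the spherical pressure boundary-value problem by finite
    differences: (1/r^2)(r^2 p')' = (alpha/R)^2 (p - p_v), p'(0)=0, p(R)=0."""
    r = np.linspace(0.0, radius, n)
    h = r[1] - r[0]
    c = (alpha / radius) ** 2
    main = np.full(n, -2.0 / h**2 - c)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    rhs = np.full(n, -c * p_v)
    for i in range(1, n - 1):
        lower[i - 1] = 1.0 / h**2 - 1.0 / (r[i] * h)
        upper[i] = 1.0 / h**2 + 1.0 / (r[i] * h)
    # r=0: symmetry => laplacian -> 3 p''(0); ghost p[-1]=p[1]
    main[0] = -6.0 / h**2 - c
    upper[0] = 6.0 / h**2
    # r=R: Dirichlet
    main[-1] = 1.0
    lower[-1] = 0.0
    rhs[-1] = 0.0
    A = diags([lower, main, upper], [-1, 0, 1], format="csc")
    return r, spsolve(A, rhs)


class TestComputeAlpha:
    def test_threshold_values_give_transition_alpha(self):
        # R=0.5 cm, CFC=2.5e-5, K=6.9e-7 -> alpha ~ 3, the regime boundary
        alpha = ittm.compute_alpha(0.5, 2.5e-5, 6.9e-7)
        assert alpha == pytest.approx(3.01, abs=0.01)
        assert round(alpha) == 3

    @pytest.mark.parametrize(
        "radius,cfc,k_int,expected",
        [(1.0, 1.0e-6, 1.0e-6, 1.0), (2.5, 4.0e-7, 4.0e-7, 2.5)],
    )
    def test_equal_conductivities_return_radius(self, radius, cfc, k_int, expected):
        assert ittm.compute_alpha(radius, cfc, k_int) == pytest.approx(expected)

    def test_nonpositive_arguments_rejected(self):
        for args in [(-1, 1e-6, 1e-6), (1, 0, 1e-6), (1, 1e-6, -2.0)]:
            with pytest.raises(ValueError):
                ittm.compute_alpha(*args)

    def test_warns_outside_physiological_range(self):
        with pytest.warns(UserWarning):
            ittm.compute_alpha(10.0, 1e-4, 1e-8)  # alpha = 1000
        with pytest.warns(UserWarning):
            ittm.compute_alpha(0.01, 1e-6, 1e-6)  # alpha = 0.01


class TestSteadyStateIFP:
    @pytest.mark.parametrize("alpha", [0.5, 3.0, 30.0, 150.0])
    def test_matches_finite_difference_oracle(self, alpha):
        p_v, R = 10.0, 1.0
        params = ittm.TransportParameters(
            cfc=1e-6 * alpha**2, k_int=1e-6, p_v=p_v, radius=R
        )
        field = ittm.steady_state_ifp(params, n_nodes=201)
        r_fd, p_fd = fd_pressure_oracle(alpha, p_v, R)
        p_ref = np.interp(field.r_grid, r_fd, p_fd)
        assert np.max(np.abs(field.p_i - p_ref)) / p_v < 1e-4

    def test_central_value_alpha3(self):
        # frozen from the finite-difference oracle: p_i(0) = 7.005 mmHg
        params = ittm.TransportParameters(cfc=9e-6, k_int=1e-6, p_v=10.0, radius=1.0)
        field = ittm.steady_state_ifp(params)
        assert field.p_peak == pytest.approx(7.005, abs=2e-3)

    def test_outer_boundary_exactly_zero(self, me180_params):
        field = ittm.steady_state_ifp(me180_params)
        assert field.p_i[-1] == 0.0

    def test_vanishing_alpha_limit(self):
        params = ittm.TransportParameters(
            cfc=1e-12, k_int=1.0, p_v=25.0, radius=1.0
        )  # alpha = 1e-6
        field = ittm.steady_state_ifp(params)
        assert np.all(field.p_i <= 1e-6 * params.p_v)

    def test_large_alpha_is_finite(self):
        params = ittm.TransportParameters(
            cfc=2.25e-2, k_int=1e-6, p_v=10.0, radius=1.0
        )  # alpha = 150
        field = ittm.steady_state_ifp(params)
        assert np.all(np.isfinite(field.p_i))
        assert np.all(np.isfinite(field.u))
        assert field.p_peak == pytest.approx(10.0, rel=1e-6)

    def test_requires_three_nodes(self, me180_params):
        with pytest.raises(ValueError):
            ittm.steady_state_ifp(me180_params, n_nodes=2)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        log_cfc=st.floats(-7, -4),
        log_k=st.floats(-8, -5),
        p_v=st.floats(1.0, 60.0),
        radius=st.floats(0.05, 3.0),
    )
    def test_profile_monotone_and_bounded(self, log_cfc, log_k, p_v, radius):
        params = ittm.TransportParameters(
            cfc=10**log_cfc, k_int=10**log_k, p_v=p_v, radius=radius
        )
        field = ittm.steady_state_ifp(params, n_nodes=101)
        assert np.all(np.diff(field.p_i) <= 1e-12 * p_v)
        assert np.all(field.p_i >= 0) and np.all(field.p_i <= p_v * (1 + 1e-12))
        assert np.all(field.u >= 0)
        assert field.u[0] == 0.0

    def test_depends_only_on_alpha_and_pressure(self):
        # rescaling cfc and k_int together leaves p_i unchanged
        a = ittm.TransportParameters(cfc=1e-5, k_int=1e-6, p_v=12.0, radius=0.8)
        b = ittm.TransportParameters(cfc=7e-5, k_int=7e-6, p_v=12.0, radius=0.8)
        fa = ittm.steady_state_ifp(a)
        fb = ittm.steady_state_ifp(b)
        np.testing.assert_allclose(fa.p_i, fb.p_i, rtol=1e-12, atol=1e-12)


class TestVelocity:
    def test_zero_at_center(self, me180_params):
        u = ittm.interstitial_velocity(me180_params, np.array([0.0]))
        assert u[0] == 0.0

    def test_rim_value_against_central_difference(self):
        # alpha=3, p_v=10 mmHg, K=1e-6, R=1 cm -> u(R) = 2.015e-5 cm/s
        params = ittm.TransportParameters(cfc=9e-6, k_int=1e-6, p_v=10.0, radius=1.0)
        u_R = ittm.interstitial_velocity(params, np.array([1.0]))[0]
        h = 1e-6
        p = lambda x: 10.0 * (1.0 - np.sinh(3 * x) / (x * np.sinh(3.0)))
        dpdr = (p(1.0 + h) - p(1.0 - h)) / (2 * h)
        assert u_R == pytest.approx(-1e-6 * dpdr, rel=1e-6)
        assert u_R == pytest.approx(2.015e-5, rel=1e-3)

    def test_flat_pressure_no_flow(self):
        params = ittm.TransportParameters(cfc=1e-12, k_int=1.0, p_v=10.0, radius=1.0)
        field = ittm.steady_state_ifp(params)
        # u scales as K p_v alpha^2 / (3R) for vanishing alpha
        assert np.all(field.u <= 2.0 * params.k_int * params.p_v * params.alpha**2)

    def test_maximal_at_rim(self, me180_params):
        field = ittm.steady_state_ifp(me180_params)
        assert np.argmax(field.u) == field.u.size - 1


class TestPeakRatio:
    def test_alpha3_value(self):
        # frozen from the profile limit at r -> 0
        assert ittm.peak_ifp_ratio(3.0) == pytest.approx(0.7005, abs=5e-4)

    def test_accepts_parameter_set(self, me180_params):
        assert ittm.peak_ifp_ratio(me180_params) == pytest.approx(
            central_ifp_fraction(3.0), rel=1e-9
        )

    def test_limits(self):
        assert ittm.peak_ifp_ratio(1e-8) < 1e-6
        assert abs(ittm.peak_ifp_ratio(150.0) - 1.0) < 1e-10

    def test_strictly_increasing_in_alpha(self):
        # strict below the float-saturation point, non-decreasing beyond
        alphas = np.geomspace(0.1, 30.0, 30)
        ratios = [ittm.peak_ifp_ratio(a) for a in alphas]
        assert np.all(np.diff(ratios) > 0)
        assert all(0 < r < 1 for r in ratios)
        tail = [ittm.peak_ifp_ratio(a) for a in (30.0, 60.0, 150.0)]
        assert np.all(np.diff(tail) >= 0)

    def test_mean_fraction_matches_profile_quadrature(self):
        from scipy.integrate import quad

        from ittm.pressure import mean_ifp_fraction

        for alpha in (0.5, 3.0, 10.0):
            num, _ = quad(
                lambda x: ifp_profile(alpha, 1.0, np.array([x]))[0] * 3 * x**2, 0, 1
            )
            assert mean_ifp_fraction(alpha) == pytest.approx(num, rel=1e-6)

    def test_profile_limit_consistency(self):
        # the x->0 profile value equals the closed-form central fraction
        x = np.array([1e-8])
        for alpha in [0.5, 3.0, 30.0]:
            p0 = ifp_profile(alpha, 1.0, x)[0]
            assert p0 == pytest.approx(central_ifp_fraction(alpha), rel=1e-6)
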