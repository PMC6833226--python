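"""Closed-form magneto-mechanics against independent oracles.

Expected numbers below were computed by hand from the printed material
constants before the implementation existed (constant-arithmetic
oracles), or by independent numerical integration.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.integrate import cumulative_simpson, cumulative_trapezoid, quad
from scipy.optimize import minimize_scalar

from spindlemag import (
    FieldSpec,
    PhysicalConstants,
    bending_moment,
    deflection,
    dimer_orientation_energy,
    dimer_orientation_pdf,
    dimer_torque,
    effective_pulling_force,
    max_deflection,
    mt_rotation_rate,
    mt_torque,
    polymerization_rate,
)
from spindlemag.errors import (
    DegenerateBendingError,
    DomainError,
    InvalidFieldError,
    InvalidGeometryError,
)

# constant-arithmetic oracle: delta_chi B^2 / (2 mu0) at B = 9 T
M0_SCALE = 1.243e-32 * 81.0 / (2.0 * 4e-7 * np.pi)  # 4.006e-25 J
# Boltzmann exponent delta_chi B^2 / (2 mu0 kB T) at 301.65 K
BOLTZ_EXP = M0_SCALE / (1.380649e-23 * 301.65)  # 9.619e-5


class TestDimerTorque:
    def test_zeros_at_aligned_and_perpendicular(self, field9, consts):
        assert dimer_torque(0.0, field9, consts) == 0.0
        assert dimer_torque(np.pi / 2, field9, consts) == pytest.approx(0.0, abs=1e-40)

    def test_maximal_torque_value(self, field9, consts):
        # 4.006e-25 N m at theta = pi/4, by direct constant arithmetic
        assert dimer_torque(np.pi / 4, field9, consts) == pytest.approx(4.006e-25, rel=1e-3)
        assert dimer_torque(np.pi / 4, field9, consts) == pytest.approx(M0_SCALE, rel=1e-12)

    def test_negative_field_rejected(self):
        with pytest.raises(InvalidFieldError):
            FieldSpec(-1.0)

    @given(theta=st.floats(-10.0, 10.0))
    def test_period_pi(self, theta):
        f, c = FieldSpec(9.0), PhysicalConstants()
        a = dimer_torque(theta, f, c)
        b = dimer_torque(theta + np.pi, f, c)
        assert a == pytest.approx(b, abs=1e-9 * M0_SCALE)


class TestOrientationEnergy:
    def test_energy_values(self, field9, consts):
        assert dimer_orientation_energy(0.0, field9, consts) == 0.0
        assert dimer_orientation_energy(np.pi / 2, field9, consts) == pytest.approx(4.006e-25, rel=1e-3)

    def test_torque_is_energy_gradient(self, field9, consts):
        # dE/dtheta = M0(theta) by central differences, 100 angles
        rng = np.random.default_rng(7)
        thetas = rng.uniform(-np.pi, np.pi, 100)
        h = 1e-6
        dE = (
            dimer_orientation_energy(thetas + h, field9, consts)
            - dimer_orientation_energy(thetas - h, field9, consts)
        ) / (2 * h)
        M = dimer_torque(thetas, field9, consts)
        assert np.all(np.abs(dE - M) < 1e-6 * M0_SCALE)

    def test_nonnegative(self, field9, consts):
        thetas = np.linspace(-np.pi, np.pi, 101)
        assert np.all(dimer_orientation_energy(thetas, field9, consts) >= 0)


class TestOrientationPdf:
    def test_field_off_is_uniform(self, field0, consts):
        thetas = np.linspace(-np.pi / 2, np.pi / 2, 11, endpoint=False)
        np.testing.assert_allclose(dimer_orientation_pdf(thetas, field0, consts), 1.0 / np.pi, rtol=1e-12)

    def test_normalizes_to_one(self, field9, consts):
        total, _ = quad(lambda t: dimer_orientation_pdf(t, field9, consts), -np.pi / 2, np.pi / 2)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_spherical_normalizes_to_one(self, field9, consts):
        total, _ = quad(lambda t: dimer_orientation_pdf(t, field9, consts, support="spherical"), 0, np.pi)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_anisotropy_ratio(self, field9, consts):
        # p(pi/2)/p(0) = exp(-delta_chi B^2 / 2 mu0 kB T) ~ exp(-9.62e-5)
        ratio = dimer_orientation_pdf(np.pi / 2 - 1e-12, field9, consts) / dimer_orientation_pdf(0.0, field9, consts)
        assert ratio == pytest.approx(np.exp(-BOLTZ_EXP), rel=1e-9)
        assert ratio == pytest.approx(np.exp(-9.62e-5), rel=1e-6)


class TestPolymerizationRate:
    def test_parallel_growth_unaffected(self, field9, consts):
        # identity: exp(0) = 1, so v(0) = v0 = 0.125 um/s even at 9 T
        assert polymerization_rate(0.0, field9, consts) == consts.v0 == 1.25e-7

    def test_field_off(self, field0, consts):
        thetas = np.linspace(0, np.pi, 7)
        np.testing.assert_array_equal(polymerization_rate(thetas, field0, consts), np.full(7, consts.v0))

    def test_perpendicular_minimum(self, field9, consts):
        v_perp = polymerization_rate(np.pi / 2, field9, consts)
        assert v_perp == pytest.approx(1.25e-7 * np.exp(-9.62e-5), rel=1e-6)
        thetas = np.linspace(0, np.pi / 2, 64)
        v = polymerization_rate(thetas, field9, consts)
        assert np.all(np.diff(v) < 0)  # strictly decreasing on [0, pi/2]

    @given(theta=st.floats(0.0, np.pi))
    def test_mirror_symmetry(self, theta):
        f, c = FieldSpec(9.0), PhysicalConstants()
        assert polymerization_rate(theta, f, c) == pytest.approx(
            polymerization_rate(np.pi - theta, f, c), rel=1e-12
        )


class TestFilamentTorque:
    def test_value_at_100um(self, field9, consts):
        # (13 L / d0) * M0 = 6.51e-20 N m for L = 100 um at pi/4
        assert mt_torque(100e-6, np.pi / 4, field9, consts) == pytest.approx(6.51e-20, rel=1e-3)

    def test_linear_in_length(self, field9, consts):
        t1 = mt_torque(50e-6, 0.3, field9, consts)
        t2 = mt_torque(100e-6, 0.3, field9, consts)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_invalid_length(self, field9, consts):
        with pytest.raises(InvalidGeometryError):
            mt_torque(0.0, 0.3, field9, consts)
        with pytest.raises(InvalidGeometryError):
            mt_torque(-1e-6, 0.3, field9, consts)


class TestRotationRate:
    def test_zero_when_aligned(self, field9, consts):
        assert mt_rotation_rate(100e-6, 0.0, field9, consts) == 0.0

    def test_magnitude(self, field9, consts):
        # 2M/(xi L^2) = 1.30e-8 rad/s for L = 100 um at pi/4
        assert mt_rotation_rate(100e-6, np.pi / 4, field9, consts) == pytest.approx(1.30e-8, rel=1e-2)

    def test_argmax_at_pi_over_4(self, field9, consts):
        res = minimize_scalar(
            lambda t: -mt_rotation_rate(100e-6, t, field9, consts),
            bounds=(0.0, np.pi / 2),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(np.pi / 4, abs=1e-6)


class TestBendingMoment:
    def test_zero_at_tip_max_at_anchor(self, field9, consts):
        L = 80e-6
        assert bending_moment(L, L, np.pi / 4, field9, consts) == pytest.approx(0.0, abs=1e-30)
        m0 = bending_moment(0.0, L, np.pi / 4, field9, consts)
        coeff = 13 * 1.243e-32 * 81 / (2 * 8e-9 * 4e-7 * np.pi)
        assert m0 == pytest.approx(coeff * L, rel=1e-9)

    def test_linear_in_remaining_length(self, field9, consts):
        L = 80e-6
        assert bending_moment(L / 2, L, 0.3, field9, consts) == pytest.approx(
            bending_moment(0.0, L, 0.3, field9, consts) / 2, rel=1e-12
        )

    def test_domain_error(self, field9, consts):
        with pytest.raises(DomainError):
            bending_moment(-1e-9, 80e-6, 0.3, field9, consts)
        with pytest.raises(DomainError):
            bending_moment(81e-6, 80e-6, 0.3, field9, consts)


class TestDeflection:
    def test_field_off_is_flat(self, field0, consts):
        prof = deflection(50e-6, 0.7, field0, consts)
        assert prof.omega_max == 0.0
        assert np.all(prof.omega == 0.0)

    def test_tip_deflection_magnitude(self, field9, consts):
        # ~0.82 um for a 50 um filament at pi/4 under 9 T
        prof = deflection(50e-6, np.pi / 4, field9, consts)
        assert prof.omega_max == pytest.approx(0.819e-6, rel=1e-2)
        assert prof.omega_max == prof.omega[-1] == np.max(prof.omega)
        assert prof.omega[0] == 0.0

    def test_clamped_boundary_slope(self, field9, consts):
        prof = deflection(50e-6, np.pi / 4, field9, consts, n_points=2001)
        slope0 = (prof.omega[1] - prof.omega[0]) / (prof.x[1] - prof.x[0])
        # omega ~ k L x^2 / 2 near 0, so the first finite-difference slope
        # is O(h); compare against the analytic value at the midpoint
        k = prof.omega_max * 3 / (50e-6) ** 3
        assert slope0 == pytest.approx(k * 50e-6 * prof.x[1] / 2, rel=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_double_quadrature(self, seed, consts):
        # independent oracle: integrate M(x)/EI twice with clamped start
        rng = np.random.default_rng(seed)
        L = rng.uniform(10e-6, 200e-6)
        theta = rng.uniform(0.05, np.pi / 2 - 0.05)
        B = rng.uniform(1.0, 12.0)
        fld = FieldSpec(B)
        x = np.linspace(0.0, L, 20001)
        curvature = bending_moment(x, L, theta, fld, consts) / consts.EI
        # trapezoid is exact for the linear curvature, Simpson for the
        # quadratic slope, so the oracle carries no discretization error
        slope = cumulative_trapezoid(curvature, x, initial=0.0)
        omega_quad = cumulative_simpson(slope, x=x, initial=0.0)
        prof = deflection(L, theta, fld, consts, n_points=20001)
        np.testing.assert_allclose(prof.omega[1:], omega_quad[1:], rtol=1e-6)
        assert prof.omega_max == pytest.approx(omega_quad[-1], rel=1e-6)

    def test_scaling_exponents(self, field9, consts):
        # omega_max ~ L^3 and ~ B^2 exactly
        w1 = max_deflection(20e-6, 0.6, field9, consts)
        w2 = max_deflection(40e-6, 0.6, field9, consts)
        assert np.log2(w2 / w1) == pytest.approx(3.0, abs=1e-6)
        w3 = max_deflection(20e-6, 0.6, FieldSpec(4.5), consts)
        assert np.log2(w1 / w3) == pytest.approx(2.0, abs=1e-6)


class TestEffectivePullingForce:
    def test_unbent_identity(self):
        assert effective_pulling_force(1.0e-12, 50e-6, 0.0) == 1.0e-12

    def test_three_four_five(self):
        # 3-4-5 triangle: f = 1 pN, L = 50 um, omega = 30 um -> 0.8 pN
        assert effective_pulling_force(1.0e-12, 50e-6, 30e-6) == pytest.approx(0.8e-12, rel=1e-12)

    def test_vanishes_in_degenerate_limit(self):
        assert effective_pulling_force(1.0, 50e-6, 50e-6 * (1 - 1e-9)) < 1e-4

    def test_degenerate_error(self):
        with pytest.raises(DegenerateBendingError):
            effective_pulling_force(1.0, 50e-6, 50e-6)

    @given(w=st.floats(0.0, 0.99), w2=st.floats(0.0, 0.99))
    def test_monotone_nonincreasing(self, w, w2):
        L = 50e-6
        lo, hi = sorted([w, w2])
        assert effective_pulling_force(1.0, L, hi * L) <= effective_pulling_force(1.0, L, lo * L)


class TestFieldOffNullifies:
    def test_all_magnetic_quantities_bitwise_zero(self, field0, consts):
        assert dimer_torque(0.37, field0, consts) == 0.0
        assert dimer_orientation_energy(0.37, field0, consts) == 0.0
        assert mt_torque(50e-6, 0.37, field0, consts) == 0.0
        assert mt_rotation_rate(50e-6, 0.37, field0, consts) == 0.0
        assert bending_moment(10e-6, 50e-6, 0.37, field0, consts) == 0.0
        assert max_deflection(50e-6, 0.37, field0, consts) == 0.0
        assert polymerization_rate(0.37, field0, consts) == consts.v0
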