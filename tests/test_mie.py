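"""Anisotropic Mie solver versus the independent isotropic oracle and
closed-form/self-consistency checks."""

from __future__ import annotations

import math

import numpy as np
import pytest

from photoglass.mie import (
    AnisotropicSphere,
    MieNumericalError,
    OpticalContext,
    default_l_max,
    effective_order,
    mie_coefficients,
    scattering_amplitudes,
    scattering_efficiency,
)

from oracles import bhmie, bhmie_amplitudes, bhmie_q_sca


class TestEffectiveOrder:
    def test_reduces_to_integer_when_isotropic(self):
        n = np.arange(1, 8)
        assert np.allclose(effective_order(n, 1.7, 1.7), n, atol=1e-14)

    def test_strong_anisotropy_value(self):
        # nu_2 = -1/2 + sqrt(1/4 + 6 (1.96/1.40)^2) for the quadrupole
        expected = -0.5 + math.sqrt(0.25 + 6.0 * (1.96 / 1.40) ** 2)
        assert effective_order(2, 1.96, 1.40) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.97, abs=0.01)


class TestIsotropicOracle:
    @pytest.mark.parametrize("d", [100.0, 305.0, 450.0, 600.0])
    @pytest.mark.parametrize("lam", [400.0, 550.0, 700.0, 900.0])
    @pytest.mark.parametrize("n", [1.4, 1.74, 1.96])
    def test_coefficients_match_oracle(self, d, lam, n):
        """n_t = n_r must reproduce an independent isotropic Mie code to 1e-8."""
        ctx = OpticalContext(1.33, lam)
        coeff = mie_coefficients(AnisotropicSphere.isotropic(d, n), ctx)
        a_o, b_o = bhmie(coeff.x, n / 1.33, coeff.l_max)
        scale = max(np.abs(a_o).max(), np.abs(b_o).max())
        assert np.abs(coeff.a - a_o).max() <= 1e-8 * scale
        assert np.abs(coeff.b - b_o).max() <= 1e-8 * scale
        assert coeff.q_sca() == pytest.approx(
            bhmie_q_sca(coeff.x, n / 1.33, coeff.l_max), rel=1e-8
        )

    def test_amplitudes_match_oracle(self):
        ctx = OpticalContext(1.33, 500.0)
        sphere = AnisotropicSphere.isotropic(305.0, 1.96)
        x = ctx.size_parameter(305.0)
        for theta in (0.0, 0.7, math.pi / 2, math.pi):
            s1, s2 = scattering_amplitudes(sphere, ctx, theta)
            s1_o, s2_o = bhmie_amplitudes(x, 1.96 / 1.33, theta)
            assert abs(s1 - s1_o) <= 1e-8 * abs(s1_o) + 1e-12
            assert abs(s2 - s2_o) <= 1e-8 * abs(s2_o) + 1e-12


class TestCoefficients:
    def test_zero_contrast_gives_zero(self):
        ctx = OpticalContext(1.33, 500.0)
        coeff = mie_coefficients(AnisotropicSphere.isotropic(305.0, 1.33), ctx)
        assert np.abs(coeff.a).max() == 0.0
        assert np.abs(coeff.b).max() == 0.0

    @pytest.mark.parametrize("nt,nr", [(1.96, 1.40), (1.40, 1.96), (2.1, 1.1)])
    def test_unitarity_bound(self, nt, nr):
        """Non-absorbing sphere: |a_n|, |b_n| <= 1 for all orders."""
        for lam in (400.0, 550.0, 900.0):
            c = mie_coefficients(
                AnisotropicSphere(305.0, nt, nr), OpticalContext(1.33, lam)
            )
            assert np.abs(c.a).max() <= 1.0 + 1e-12
            assert np.abs(c.b).max() <= 1.0 + 1e-12

    def test_te_coefficients_independent_of_radial_index(self):
        """b_n see only the tangential index: exact n_r independence."""
        ctx = OpticalContext(1.33, 520.0)
        b_ref = mie_coefficients(AnisotropicSphere(305.0, 1.87, 1.40), ctx).b
        for nr in (1.45, 1.52, 1.60):
            b = mie_coefficients(AnisotropicSphere(305.0, 1.87, nr), ctx).b
            assert np.allclose(b, b_ref, rtol=0, atol=1e-15)

    def test_continuity_at_isotropic_point(self):
        """Q_sca continuous in (n_t, n_r) around n_t = n_r."""
        lams = np.arange(400.0, 701.0, 25.0)
        q0 = scattering_efficiency(AnisotropicSphere(305.0, 1.7, 1.7), lams).q_sca
        eps = 1e-6
        for sphere in (
            AnisotropicSphere(305.0, 1.7 + eps, 1.7),
            AnisotropicSphere(305.0, 1.7, 1.7 + eps),
        ):
            q1 = scattering_efficiency(sphere, lams).q_sca
            assert np.abs(q1 - q0).max() < 1e-4  # finite-difference slope O(1)

    def test_nonfinite_bessel_raises(self):
        with pytest.raises(MieNumericalError):
            mie_coefficients(
                AnisotropicSphere(305.0, 1.96, 1.40),
                OpticalContext(1.33, 1e12),  # x ~ 1e-9 at high order: yv overflows
                l_max=120,
            )


class TestEfficiencySpectrum:
    def test_zero_contrast_spectrum_is_zero(self):
        lams = np.arange(400.0, 901.0, 50.0)
        spec = scattering_efficiency(AnisotropicSphere.isotropic(305.0, 1.33), lams)
        assert np.all(spec.q_sca == 0.0)

    def test_matches_oracle_across_grid(self):
        lams = np.arange(400.0, 901.0, 10.0)
        spec = scattering_efficiency(
            AnisotropicSphere.isotropic(305.0, 1.96), lams, n_medium=1.33
        )
        for lam, q in zip(lams, spec.q_sca):
            x = math.pi * 305.0 * 1.33 / lam
            assert q == pytest.approx(bhmie_q_sca(x, 1.96 / 1.33), rel=1e-8)

    def test_channels_sum_to_total(self):
        lams = np.arange(400.0, 701.0, 20.0)
        spec = scattering_efficiency(
            AnisotropicSphere(305.0, 1.96, 1.40), lams, per_multipole=True
        )
        total = sum(spec.per_multipole.values())
        assert np.abs(total - spec.q_sca).max() <= 1e-10 * spec.q_sca.max()
        assert np.all(spec.q_sca >= 0.0)

    def test_te2_te3_dominate_visible_for_measured_particle(self):
        """At the single-particle measurement size the quadrupole+octupole TE
        channels carry more of the visible band than any other channel."""
        lams = np.arange(400.0, 751.0, 5.0)
        spec = scattering_efficiency(
            AnisotropicSphere(450.0, 1.96, 1.40), lams, n_medium=1.0,
            per_multipole=True,
        )
        integrals = {
            key: np.trapezoid(vals, lams) for key, vals in spec.per_multipole.items()
        }
        te23 = integrals[("TE", 2)] + integrals[("TE", 3)]
        others = max(
            v for k, v in integrals.items() if k not in [("TE", 2), ("TE", 3)]
        )
        assert te23 > others

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            scattering_efficiency(AnisotropicSphere.isotropic(305.0, 1.96), np.array([]))

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            scattering_efficiency(
                AnisotropicSphere.isotropic(305.0, 1.96), np.array([500.0, 450.0])
            )


class TestAmplitudes:
    def test_angular_integral_reproduces_efficiency(self):
        """Integrated unpolarised differential cross-section = Q_sca."""
        ctx = OpticalContext(1.33, 500.0)
        sphere = AnisotropicSphere(305.0, 1.96, 1.40)
        theta = np.linspace(0.0, math.pi, 4001)
        s1, s2 = scattering_amplitudes(sphere, ctx, theta)
        integrand = (np.abs(s1) ** 2 + np.abs(s2) ** 2) * np.sin(theta)
        sigma = np.trapezoid(integrand, theta) * math.pi / ctx.k**2
        q = sigma / (math.pi * (305.0 / 2.0) ** 2)
        coeff = mie_coefficients(sphere, ctx)
        assert q == pytest.approx(coeff.q_sca(), rel=1e-4)

    def test_optical_theorem_for_nonabsorbing_sphere(self):
        """Extinction from the forward amplitude equals scattering."""
        ctx = OpticalContext(1.33, 500.0)
        for sphere in (
            AnisotropicSphere.isotropic(305.0, 1.96),
            AnisotropicSphere(305.0, 1.96, 1.40),
        ):
            coeff = mie_coefficients(sphere, ctx)
            s1_fwd, _ = scattering_amplitudes(sphere, ctx, 0.0)
            q_ext = 4.0 / coeff.x**2 * s1_fwd.real
            assert q_ext == pytest.approx(coeff.q_sca(), rel=1e-4)

    def test_endpoint_angles_finite(self):
        ctx = OpticalContext(1.33, 500.0)
        sphere = AnisotropicSphere(305.0, 1.96, 1.40)
        for angle in (0.0, math.pi):
            s1, s2 = scattering_amplitudes(sphere, ctx, angle)
            assert np.isfinite(s1) and np.isfinite(s2)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(ValueError):
            scattering_amplitudes(
                AnisotropicSphere.isotropic(305.0, 1.96),
                OpticalContext(1.33, 500.0),
                3.5,
            )


class TestLMax:
    def test_floor_of_three(self):
        assert default_l_max(1e-6) == 3

    def test_monotone_in_size_parameter(self):
        xs = np.linspace(0.1, 50.0, 200)
        vals = [default_l_max(x) for x in xs]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_default_is_converged(self):
        """Doubling l_max beyond the default changes Q_sca by < 1e-8."""
        ctx = OpticalContext(1.33, 400.0)
        sphere = AnisotropicSphere.isotropic(305.0, 1.96)
        q1 = mie_coefficients(sphere, ctx).q_sca()
        lm = default_l_max(ctx.size_parameter(305.0))
        q2 = mie_coefficients(sphere, ctx, l_max=2 * lm).q_sca()
        assert q2 == pytest.approx(q1, rel=1e-8)

    def test_invalid_size_parameter(self):
        with pytest.raises(ValueError):
            default_l_max(0.0)


class TestDomainTypes:
    def test_sphere_invariants(self):
        with pytest.raises(ValueError):
            AnisotropicSphere(-1.0, 1.5, 1.5)
        with pytest.raises(ValueError):
            AnisotropicSphere(305.0, 0.9, 1.5)
        assert AnisotropicSphere(305.0, 1.5, 1.5).is_isotropic
        assert not AnisotropicSphere(305.0, 1.96, 1.40).is_isotropic

    def test_context_invariants(self):
        with pytest.raises(ValueError):
            OpticalContext(0.5, 500.0)
        with pytest.raises(ValueError):
            OpticalContext(1.33, -10.0)
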