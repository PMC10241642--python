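"""Dependent-scattering mean free paths and slab diffusion reflectance."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoglass.mie import AnisotropicSphere, OpticalContext, scattering_amplitudes
from photoglass.transport import (
    AssemblySpec,
    fill_fraction_sweep,
    mean_free_paths,
    reflectance_spectrum,
    slab_reflectance,
)

from oracles import brute_force_cross_section


def _mono(particle, phi, **kw):
    return AssemblySpec(particle=particle, phi=phi, sigma1=0.0, **kw)


class TestMeanFreePaths:
    def test_independent_limit_matches_mie_cross_section(self):
        """S = 1, dilute: l_s equals 1/(rho sigma_sca) from the amplitudes."""
        particle = AnisotropicSphere.isotropic(305.0, 1.96)
        spec = _mono(particle, 0.01, structure="none")
        lam = 550.0
        l_s, l_t = mean_free_paths(spec, lam)
        ctx = OpticalContext(1.33, lam)
        sigma = brute_force_cross_section(
            lambda th: scattering_amplitudes(particle, ctx, th), ctx.k
        )
        rho = 0.01 / (math.pi / 6.0 * 305.0**3)
        assert l_s == pytest.approx(1.0 / (rho * sigma), rel=1e-3)
        assert l_t >= l_s

    def test_density_linearity_with_fixed_structure(self):
        """Halving phi (hence rho) doubles both lengths when S(q) is fixed."""
        particle = AnisotropicSphere.isotropic(305.0, 1.96)
        a = _mono(particle, 0.02, structure="none")
        b = _mono(particle, 0.01, structure="none")
        ls_a, lt_a = mean_free_paths(a, 550.0)
        ls_b, lt_b = mean_free_paths(b, 550.0)
        assert ls_b == pytest.approx(2.0 * ls_a, rel=1e-6)
        assert lt_b == pytest.approx(2.0 * lt_a, rel=1e-6)

    def test_dense_value_against_fine_grid_quadrature(self):
        """phi=0.50, isotropic 1.96, 550 nm versus a brute-force oracle."""
        from photoglass.structure import py_structure_factor

        particle = AnisotropicSphere.isotropic(305.0, 1.96)
        spec = _mono(particle, 0.50)
        l_s, l_t = mean_free_paths(spec, 550.0)

        ctx = OpticalContext(1.33, 550.0)
        theta = np.linspace(0.0, math.pi, 20001)
        s1, s2 = scattering_amplitudes(particle, ctx, theta)
        dcs = (np.abs(s1) ** 2 + np.abs(s2) ** 2) / (2.0 * ctx.k**2)
        s_q = py_structure_factor(
            0.50, 305.0, 2.0 * ctx.k * np.sin(theta / 2.0)
        ).s
        rho = 0.50 / (math.pi / 6.0 * 305.0**3)
        inv_ls = rho * 2 * math.pi * np.trapezoid(dcs * s_q * np.sin(theta), theta)
        inv_lt = rho * 2 * math.pi * np.trapezoid(
            dcs * s_q * (1 - np.cos(theta)) * np.sin(theta), theta
        )
        assert l_s == pytest.approx(1.0 / inv_ls, rel=1e-3)
        assert l_t == pytest.approx(1.0 / inv_lt, rel=1e-3)

    def test_zero_contrast_returns_infinite_lengths(self):
        spec = _mono(AnisotropicSphere.isotropic(305.0, 1.33), 0.3)
        l_s, l_t = mean_free_paths(spec, 550.0)
        assert math.isinf(l_s) and math.isinf(l_t)

    def test_effective_host_reduces_to_medium_at_dilution(self):
        spec = _mono(
            AnisotropicSphere.isotropic(305.0, 1.96), 1e-6,
            host_model="maxwell_garnett",
        )
        assert spec.host_index() == pytest.approx(1.33, abs=1e-5)


class TestSlabReflectance:
    def test_closed_form_at_thickness_equal_lt(self):
        # T = (5/3)/(7/3) = 5/7 when L = l_t and z_e = (2/3) l_t
        assert slab_reflectance(1000.0, 1000.0) == pytest.approx(2.0 / 7.0, rel=1e-12)

    def test_thick_limit_full_reflectance(self):
        assert slab_reflectance(100.0, 1e9) == pytest.approx(1.0, abs=1e-5)

    def test_zero_contrast_reflects_nothing(self):
        assert slab_reflectance(math.inf, 5000.0) == 0.0

    @given(lt=st.floats(1.0, 1e7), length=st.floats(1.0, 1e6))
    @settings(max_examples=100, deadline=None)
    def test_bounds_hold_everywhere(self, lt, length):
        r = slab_reflectance(lt, length)
        assert 0.0 <= r <= 1.0

    def test_monotone_in_thickness(self):
        ls = [slab_reflectance(1000.0, L) for L in (500.0, 1000.0, 5000.0, 50000.0)]
        assert all(b >= a for a, b in zip(ls, ls[1:]))

    def test_invalid_thickness(self):
        with pytest.raises(ValueError):
            slab_reflectance(1000.0, 0.0)


class TestReflectanceSpectrum:
    def test_zero_contrast_assembly_reflects_nothing(self):
        spec = _mono(AnisotropicSphere.isotropic(305.0, 1.33), 0.5)
        tr = reflectance_spectrum(spec, 5000.0, np.arange(400.0, 701.0, 50.0))
        assert np.all(tr.reflectance == 0.0)
        assert tr.r_vis == 0.0

    def test_low_polydispersity_structural_peak_in_blue_green(self, small_packing):
        """A dense low-polydispersity glass reflects with a visible-band peak
        near 500 nm; 10% polydispersity flattens it."""
        from photoglass.glass import GlassRecipe, generate_packing
        from photoglass.structure import structure_factor_from_config

        narrow = generate_packing(
            GlassRecipe(n_particles=216, sigma1=1.0, target_fill=0.5,
                        quench_steps=4000, seed=8)
        )
        lams = np.arange(400.0, 701.0, 10.0)
        particle = AnisotropicSphere.isotropic(305.0, 1.96)

        sq_narrow = structure_factor_from_config(narrow, q_max=0.06)
        tr_narrow = reflectance_spectrum(
            AssemblySpec(particle=particle, phi=0.5, sigma1=1.0,
                         structure=sq_narrow),
            5000.0, lams,
        )
        r = tr_narrow.reflectance
        interior = (np.diff(np.sign(np.diff(r))) < 0).nonzero()[0] + 1
        bumps = lams[interior]
        assert np.any((bumps >= 450.0) & (bumps <= 600.0))

        sq_wide = structure_factor_from_config(small_packing, q_max=0.06)
        tr_wide = reflectance_spectrum(
            AssemblySpec(particle=particle, phi=0.5, sigma1=31.0,
                         structure=sq_wide),
            5000.0, lams,
        )
        ratio_narrow = tr_narrow.reflectance.max() / tr_narrow.reflectance.mean()
        ratio_wide = tr_wide.reflectance.max() / tr_wide.reflectance.mean()
        assert ratio_wide < ratio_narrow

    def test_no_nans_across_band(self):
        spec = _mono(AnisotropicSphere(305.0, 1.96, 1.40), 0.6)
        tr = reflectance_spectrum(spec, 5000.0, np.arange(400.0, 701.0, 25.0))
        assert np.all(np.isfinite(tr.reflectance))
        assert np.all((tr.reflectance >= 0) & (tr.reflectance <= 1))


class TestFillFractionSweep:
    def test_single_point_grid_is_its_own_argmax(self):
        res = fill_fraction_sweep(
            {"iso": AnisotropicSphere.isotropic(305.0, 1.96)},
            [0.4], 5000.0, np.arange(450.0, 651.0, 50.0), sigma1=0.0,
        )
        assert res["iso"]["argmax_phi"] == 0.4

    def test_isotropic_variants_peak_at_intermediate_fill(self):
        """Crowding: isotropic assemblies have an interior optimum and decline
        at high fill; the birefringent assembly does not collapse."""
        phis = np.arange(0.10, 0.7001, 0.10)
        lams = np.arange(420.0, 681.0, 40.0)
        res = fill_fraction_sweep(
            {
                "iso196": AnisotropicSphere.isotropic(305.0, 1.96),
                "biref": AnisotropicSphere(305.0, 1.96, 1.40),
            },
            phis, 5000.0, lams, sigma1=0.0,
        )
        iso = res["iso196"]["r_vis"]
        assert 0.15 <= res["iso196"]["argmax_phi"] <= 0.45
        assert iso[-1] < 0.5 * iso.max()  # strong decline beyond the optimum
        biref = res["biref"]["r_vis"]
        assert biref[-1] >= 0.8 * biref.max()  # birefringent stays high

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            fill_fraction_sweep(
                {"iso": AnisotropicSphere.isotropic(305.0, 1.96)},
                [0.8], 5000.0, np.arange(450.0, 651.0, 50.0),
            )
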