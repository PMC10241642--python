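"""Dependent-scattering transport model of photonic-glass slab reflectance.

Maps single-particle optics plus interparticle structure to a diffuse
reflectance spectrum, at desk scale, in three steps:

1. **Dependent scattering.**  The differential scattering cross-section of
   a particle embedded in the assembly is the single-particle (Mie) one
   weighted by the static structure factor at the momentum transfer
   ``q = 2 k sin(theta/2)``:

       dsigma_dep/dOmega = dsigma_Mie/dOmega(theta) * S(q),

   number-averaged over the particle-size distribution (the decoupling
   treatment: measured or analytic number-number S(q) with size-averaged
   form factors — adequate at the polydispersities of interest, <~16%).

2. **Mean free paths.**  With number density rho = phi / <(pi/6) d^3>,

       1/l_s = rho * int dsigma_dep/dOmega dOmega,
       1/l_t = rho * int dsigma_dep/dOmega (1 - cos theta) dOmega,

   by Gauss--Legendre quadrature in cos(theta), refined until converged.

The scattering contrast can optionally be renormalised for dense packings
(``host_model="maxwell_garnett"``): the particle is then embedded in a
Maxwell--Garnett effective host built from the medium and the
volume-averaged particle permittivity at the assembly's filling fraction.
As phi grows the host index approaches the particle index, the per-particle
scattering contrast collapses, and the visible reflectance develops the
interior optimum characteristic of optical crowding.  The bare host
(``host_model="bare"``, the default) is the classic dependent-scattering
model, accurate at low-to-moderate fills but with no crowding mechanism at
all; filling-fraction sweeps therefore default to the effective host.

3. **Slab diffusion.**  For a non-absorbing slab of thickness L with
   extrapolation length z_e = (2/3) l_t the diffuse transmittance is
   T = (l_t + z_e)/(L + 2 z_e) and R = 1 - T (clamped to [0, 1]; in the
   ballistic regime l_t >> L the diffusion picture degrades and R -> 0).

Birefringent particles enter at the form-factor level through the
radially anisotropic Mie amplitudes; the near-field decoupling effect of
birefringence is a separate, explicitly near-field phenomenon and is
exercised in the two-sphere coupled-dipole module, not injected here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.stats import lognorm

from photoglass.glass import lognormal_params
from photoglass.mie import AnisotropicSphere, OpticalContext, scattering_amplitudes
from photoglass.structure import StructureFactor, py_structure_factor

__all__ = [
    "AssemblySpec",
    "TransportResult",
    "mean_free_paths",
    "slab_reflectance",
    "reflectance_spectrum",
    "fill_fraction_sweep",
    "VISIBLE_BAND",
]

VISIBLE_BAND = (400.0, 700.0)


@dataclass(frozen=True)
class AssemblySpec:
    """A particle assembly: optics, size distribution, fill and structure.

    ``particle`` fixes the refractive indices; its diameter field is the
    mean of the size distribution (``mu1``).  ``structure`` selects the
    structure-factor source: the analytic Percus--Yevick fast path (default)
    at the assembly's phi and mean diameter, or a measured
    :class:`StructureFactor` from coordinates.  ``n_size_nodes`` quantile
    nodes discretise the clipped log-normal size law for number averaging;
    ``sigma1 = 0`` collapses to the monodisperse case.
    """

    particle: AnisotropicSphere
    phi: float
    sigma1: float = 31.0
    d_min: float = 100.0
    d_max: float = 600.0
    n_medium: float = 1.33
    structure: Union[str, StructureFactor] = "percus_yevick"
    n_size_nodes: int = 11
    host_model: str = "bare"

    def __post_init__(self) -> None:
        if not (0.0 < self.phi < 0.72):
            raise ValueError("phi must lie in (0, 0.72)")
        if self.host_model not in ("bare", "maxwell_garnett"):
            raise ValueError(f"unknown host_model {self.host_model!r}")

    def host_index(self) -> float:
        """Refractive index of the embedding host seen by one scatterer.

        "bare": the pure medium.  "maxwell_garnett": the MG mixture of the
        medium with the (orientation-averaged) particle permittivity
        (2 eps_t + eps_r)/3 at this phi.
        """
        if self.host_model == "bare":
            return self.n_medium
        eps_m = self.n_medium**2
        eps_p = (2.0 * self.particle.n_t**2 + self.particle.n_r**2) / 3.0
        f = self.phi
        eps_eff = eps_m * (
            (eps_p + 2.0 * eps_m + 2.0 * f * (eps_p - eps_m))
            / (eps_p + 2.0 * eps_m - f * (eps_p - eps_m))
        )
        return math.sqrt(eps_eff)

    @property
    def mu1(self) -> float:
        return self.particle.diameter

    def size_nodes(self) -> Tuple[np.ndarray, np.ndarray]:
        """(diameters, weights) — midpoint-quantile nodes of the size law."""
        if self.sigma1 == 0 or self.n_size_nodes == 1:
            return np.array([self.mu1]), np.array([1.0])
        mu2, s2sq = lognormal_params(self.mu1, self.sigma1)
        qs = (np.arange(self.n_size_nodes) + 0.5) / self.n_size_nodes
        d = lognorm.ppf(qs, s=math.sqrt(s2sq), scale=math.exp(mu2))
        d = np.clip(d, self.d_min, self.d_max)
        w = np.full(d.shape, 1.0 / d.size)
        return d, w

    def number_density(self) -> float:
        """rho in nm^-3 from phi and the number-averaged particle volume."""
        d, w = self.size_nodes()
        mean_vol = float(np.sum(w * math.pi / 6.0 * d**3))
        return self.phi / mean_vol

    def structure_factor(self, q: np.ndarray) -> np.ndarray:
        if isinstance(self.structure, StructureFactor):
            sf = self.structure
            # beyond the measured grid S -> 1; below it, hold the first value
            return np.interp(q, sf.q, sf.s, left=float(sf.s[0]), right=1.0)
        if self.structure == "percus_yevick":
            return py_structure_factor(self.phi, self.mu1, q, allow_metastable=True).s
        if self.structure == "none":
            return np.ones_like(q)
        raise ValueError(f"unknown structure source {self.structure!r}")


@dataclass
class TransportResult:
    """Reflectance spectrum of a slab plus the transport quantities behind it."""

    wavelengths: np.ndarray
    l_s: np.ndarray
    l_t: np.ndarray
    thickness: float
    reflectance: np.ndarray
    r_vis: float
    meta: dict = field(default_factory=dict)


def _differential_cross_section(
    assembly: AssemblySpec, wavelength: float, mu: np.ndarray
) -> np.ndarray:
    """Size-averaged dsigma/dOmega (nm^2/sr) at scattering angles acos(mu)."""
    theta = np.arccos(np.clip(mu, -1.0, 1.0))
    ctx = OpticalContext(assembly.host_index(), wavelength)
    k = ctx.k
    d_nodes, w_nodes = assembly.size_nodes()
    dcs = np.zeros_like(mu)
    for d, w in zip(d_nodes, w_nodes):
        sphere = replace(assembly.particle, diameter=float(d))
        s1, s2 = scattering_amplitudes(sphere, ctx, theta)
        dcs += w * (np.abs(s1) ** 2 + np.abs(s2) ** 2) / (2.0 * k**2)
    return dcs


def mean_free_paths(
    assembly: AssemblySpec,
    wavelength: float,
    n_angle: int = 128,
    rtol: float = 1.0e-4,
    max_n_angle: int = 1024,
) -> Tuple[float, float]:
    """Scattering and transport mean free paths (nm) at one vacuum wavelength.

    Gauss--Legendre quadrature in cos(theta), doubling the node count until
    1/l_t changes by less than ``rtol``.

    Raises
    ------
    RuntimeError
        If the quadrature has not converged at ``max_n_angle`` nodes.
    """
    rho = assembly.number_density()
    k = 2.0 * math.pi * assembly.host_index() / wavelength

    def inverse_lengths(n_nodes: int) -> Tuple[float, float]:
        mu, w = np.polynomial.legendre.leggauss(n_nodes)
        dcs = _differential_cross_section(assembly, wavelength, mu)
        q = 2.0 * k * np.sin(np.arccos(np.clip(mu, -1, 1)) / 2.0)
        s_q = assembly.structure_factor(q)
        integrand = dcs * s_q
        sigma = 2.0 * math.pi * np.sum(w * integrand)
        sigma_tr = 2.0 * math.pi * np.sum(w * integrand * (1.0 - mu))
        return rho * sigma, rho * sigma_tr

    inv_ls, inv_lt = inverse_lengths(n_angle)
    n = n_angle
    while n < max_n_angle:
        n *= 2
        inv_ls2, inv_lt2 = inverse_lengths(n)
        if abs(inv_lt2 - inv_lt) <= rtol * abs(inv_lt2) and abs(
            inv_ls2 - inv_ls
        ) <= rtol * abs(inv_ls2):
            inv_ls, inv_lt = inv_ls2, inv_lt2
            break
        inv_ls, inv_lt = inv_ls2, inv_lt2
    else:
        raise RuntimeError(
            f"angular quadrature did not converge at {max_n_angle} nodes "
            f"(lambda={wavelength} nm, phi={assembly.phi})"
        )
    if inv_ls <= 0 or inv_lt <= 0:
        return math.inf, math.inf
    return 1.0 / inv_ls, 1.0 / inv_lt


def slab_reflectance(l_t, thickness: float):
    """Diffuse reflectance of a non-absorbing slab from its transport length.

    R = 1 - (l_t + z_e)/(L + 2 z_e) with z_e = (2/3) l_t, clamped to [0, 1]:
    zero-contrast assemblies (l_t = inf) reflect nothing, optically thick
    slabs (L >> l_t) approach full reflectance.
    """
    if thickness <= 0:
        raise ValueError("slab thickness must be positive")
    l_t_arr = np.asarray(l_t, dtype=float)
    z_e = (2.0 / 3.0) * l_t_arr
    with np.errstate(invalid="ignore"):
        t = (l_t_arr + z_e) / (thickness + 2.0 * z_e)
    t = np.where(np.isfinite(l_t_arr), t, 1.0)
    r = np.clip(1.0 - t, 0.0, 1.0)
    if r.ndim == 0:
        return float(r)
    return r


def reflectance_spectrum(
    assembly: AssemblySpec,
    thickness: float,
    wavelengths: Sequence[float],
) -> TransportResult:
    """R(lambda) for a slab, plus the visible-band mean reflectance R_vis."""
    lams = np.asarray(wavelengths, dtype=float)
    if lams.size == 0 or np.any(np.diff(lams) <= 0):
        raise ValueError("wavelength grid must be non-empty and increasing")
    l_s = np.empty_like(lams)
    l_t = np.empty_like(lams)
    for i, lam in enumerate(lams):
        l_s[i], l_t[i] = mean_free_paths(assembly, float(lam))
    refl = slab_reflectance(l_t, thickness)
    vis = (lams >= VISIBLE_BAND[0]) & (lams <= VISIBLE_BAND[1])
    r_vis = float(np.mean(refl[vis])) if np.any(vis) else float("nan")
    return TransportResult(
        wavelengths=lams,
        l_s=l_s,
        l_t=l_t,
        thickness=thickness,
        reflectance=refl,
        r_vis=r_vis,
        meta={
            "phi": assembly.phi,
            "n_medium": assembly.n_medium,
            "particle": {
                "diameter": assembly.particle.diameter,
                "n_t": assembly.particle.n_t,
                "n_r": assembly.particle.n_r,
            },
        },
    )


def fill_fraction_sweep(
    variants: Dict[str, AnisotropicSphere],
    phis: Sequence[float],
    thickness: float,
    wavelengths: Sequence[float],
    sigma1: float = 31.0,
    n_medium: float = 1.33,
    structure: str = "percus_yevick",
    host_model: str = "maxwell_garnett",
) -> Dict[str, dict]:
    """R_vis(phi) per particle variant, with the grid argmax.

    Sweeps default to the Maxwell--Garnett effective host: without the
    contrast renormalisation the model has no optical-crowding mechanism and
    R_vis cannot develop the interior optimum these sweeps exist to study.

    Returns ``{name: {"phi": array, "r_vis": array, "argmax_phi": float}}``.
    """
    phis = np.asarray(phis, dtype=float)
    if phis.size == 0 or np.any((phis <= 0) | (phis > 0.70 + 1e-9)):
        raise ValueError("phi grid must be non-empty within (0, 0.70]")
    out: Dict[str, dict] = {}
    for name, particle in variants.items():
        r_vis = np.empty_like(phis)
        for i, phi in enumerate(phis):
            spec = AssemblySpec(
                particle=particle,
                phi=float(phi),
                sigma1=sigma1,
                n_medium=n_medium,
                structure=structure,
                host_model=host_model,
            )
            r_vis[i] = reflectance_spectrum(spec, thickness, wavelengths).r_vis
        out[name] = {
            "phi": phis.copy(),
            "r_vis": r_vis,
            "argmax_phi": float(phis[int(np.argmax(r_vis))]),
        }
    return out
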