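"""Mie scattering for spheres with radially oriented uniaxial anisotropy.

A spherulitic nanosphere (for example an isoxanthopterin organelle, whose
stacked molecular planes project radially from the particle centre) presents
a *tangential* refractive index ``n_t`` to fields oriented along the sphere
surface and a *radial* index ``n_r`` along the surface normal.  For such a
radially anisotropic sphere the transverse-electric (TE, magnetic-type
``b_n``) partial waves see only ``n_t`` and are identical to the isotropic
Mie coefficients evaluated at the tangential relative index.  The
transverse-magnetic (TM, electric-type ``a_n``) partial waves couple both
indices: inside the sphere the radial Riccati--Bessel function acquires a
*fractional* effective order

    nu_n = -1/2 + sqrt(1/4 + n(n+1) * (n_t/n_r)**2),

which reduces to the integer order ``n`` in the isotropic limit
``n_t == n_r``.  Coefficients follow the Bohren--Huffman sign convention
(time dependence ``exp(-i omega t)``, outgoing ``xi_n = x h_n^(1)(x)``).

All Bessel evaluations go through :func:`scipy.special.jv`/``yv`` at
half-integer or fractional order; the parameter regimes of interest
(size parameters x <~ 10) are numerically benign for direct evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import special

__all__ = [
    "AnisotropicSphere",
    "OpticalContext",
    "MultipoleCoefficients",
    "ScatteringSpectrum",
    "MieNumericalError",
    "default_l_max",
    "effective_order",
    "mie_coefficients",
    "scattering_efficiency",
    "scattering_amplitudes",
]


class MieNumericalError(FloatingPointError):
    """Raised when Bessel-function evaluation produces non-finite values."""


@dataclass(frozen=True)
class AnisotropicSphere:
    """Geometry and optical axes of one radially anisotropic sphere.

    Parameters
    ----------
    diameter : float
        Particle diameter in nm.
    n_t : float
        Tangential refractive index (in the sphere-surface plane).
    n_r : float
        Radial refractive index (along the surface normal).  Equal indices
        describe an ordinary isotropic sphere.
    """

    diameter: float
    n_t: float
    n_r: float

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be positive, got {self.diameter}")
        if self.n_t < 1 or self.n_r < 1:
            raise ValueError("refractive indices must be >= 1")

    @property
    def is_isotropic(self) -> bool:
        return self.n_t == self.n_r

    @classmethod
    def isotropic(cls, diameter: float, n: float) -> "AnisotropicSphere":
        return cls(diameter=diameter, n_t=n, n_r=n)


@dataclass(frozen=True)
class OpticalContext:
    """Host medium and vacuum wavelength (nm) of one calculation."""

    n_medium: float
    wavelength: float

    def __post_init__(self) -> None:
        if self.n_medium < 1:
            raise ValueError("n_medium must be >= 1")
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")

    @property
    def k(self) -> float:
        """Wavenumber in the medium, nm^-1."""
        return 2.0 * math.pi * self.n_medium / self.wavelength

    def size_parameter(self, diameter: float) -> float:
        return self.k * diameter / 2.0


@dataclass(frozen=True)
class MultipoleCoefficients:
    """Mie coefficients a_n (TM/electric) and b_n (TE/magnetic), n = 1..l_max."""

    l_max: int
    a: np.ndarray
    b: np.ndarray
    x: float
    m_t: float
    m_r: float
    nu: np.ndarray

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, self.l_max + 1)

    def q_sca(self) -> float:
        n = self.orders
        return float(
            (2.0 / self.x**2)
            * np.sum((2 * n + 1) * (np.abs(self.a) ** 2 + np.abs(self.b) ** 2))
        )

    def q_ext(self) -> float:
        n = self.orders
        return float((2.0 / self.x**2) * np.sum((2 * n + 1) * np.real(self.a + self.b)))


@dataclass
class ScatteringSpectrum:
    """Scattering efficiency on a wavelength grid, optionally per multipole.

    ``per_multipole`` maps ``("TE"|"TM", order)`` to that channel's
    contribution to Q_sca; channel contributions sum exactly to the total.
    """

    wavelengths: np.ndarray
    q_sca: np.ndarray
    per_multipole: Optional[Dict[Tuple[str, int], np.ndarray]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.q_sca = np.asarray(self.q_sca, dtype=float)
        if self.wavelengths.size == 0:
            raise ValueError("empty wavelength grid")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.wavelengths.shape != self.q_sca.shape:
            raise ValueError("wavelengths and q_sca shapes differ")


def default_l_max(x: float) -> int:
    """Truncation order adequate for ~1e-8 converged Q_sca.

    Wiscombe-style rule ``ceil(x + 4.05 x^(1/3) + 2)`` with a floor of 3 so
    that the quadrupole (TE2) and octupole (TE3) channels always exist.
    """
    if not x > 0:
        raise ValueError("size parameter must be positive")
    return max(3, int(math.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0)))


def effective_order(n: np.ndarray | int, n_t: float, n_r: float) -> np.ndarray:
    """Fractional radial-wave order nu_n of the TM partial wave."""
    n = np.asarray(n, dtype=float)
    return -0.5 + np.sqrt(0.25 + n * (n + 1.0) * (n_t / n_r) ** 2)


def _riccati_psi(order: np.ndarray, z: float) -> Tuple[np.ndarray, np.ndarray]:
    """psi_nu(z) = sqrt(pi z / 2) J_{nu+1/2}(z) and its derivative.

    Valid for arbitrary real order; the derivative uses the downward
    recurrence psi'_nu = psi_{nu-1} - (nu/z) psi_nu.
    """
    order = np.asarray(order, dtype=float)
    pref = math.sqrt(math.pi * z / 2.0)
    psi = pref * special.jv(order + 0.5, z)
    psi_m1 = pref * special.jv(order - 0.5, z)
    dpsi = psi_m1 - (order / z) * psi
    return psi, dpsi


def _riccati_xi(order: np.ndarray, z: float) -> Tuple[np.ndarray, np.ndarray]:
    """xi_n(z) = z h_n^(1)(z) as a Riccati--Bessel function, plus derivative."""
    order = np.asarray(order, dtype=float)
    pref = math.sqrt(math.pi * z / 2.0)
    with np.errstate(invalid="ignore", over="ignore"):
        jn = special.jv(order + 0.5, z)
        yn = special.yv(order + 0.5, z)
        jm = special.jv(order - 0.5, z)
        ym = special.yv(order - 0.5, z)
        xi = pref * (jn + 1j * yn)
        xi_m1 = pref * (jm + 1j * ym)
    dxi = xi_m1 - (order / z) * xi
    return xi, dxi


def mie_coefficients(
    sphere: AnisotropicSphere, ctx: OpticalContext, l_max: Optional[int] = None
) -> MultipoleCoefficients:
    """Multipole coefficients of a radially anisotropic sphere.

    TE (``b_n``) coefficients are isotropic Mie coefficients at relative
    index ``m_t = n_t/n_medium``; TM (``a_n``) coefficients replace the
    interior Riccati--Bessel order ``n`` by the fractional ``nu_n``.

    Raises
    ------
    MieNumericalError
        If any Bessel evaluation is non-finite (extreme x or order).
    """
    x = ctx.size_parameter(sphere.diameter)
    if l_max is None:
        l_max = default_l_max(x)
    if l_max < 1:
        raise ValueError("l_max must be >= 1")

    m_t = sphere.n_t / ctx.n_medium
    m_r = sphere.n_r / ctx.n_medium
    n = np.arange(1, l_max + 1, dtype=float)
    nu = effective_order(n, sphere.n_t, sphere.n_r)

    psi_x, dpsi_x = _riccati_psi(n, x)
    xi_x, dxi_x = _riccati_xi(n, x)
    # interior radial functions: integer order for TE, fractional for TM
    psi_mx_te, dpsi_mx_te = _riccati_psi(n, m_t * x)
    psi_mx_tm, dpsi_mx_tm = _riccati_psi(nu, m_t * x)

    for arr in (psi_x, dpsi_x, xi_x, dxi_x, psi_mx_te, dpsi_mx_te, psi_mx_tm, dpsi_mx_tm):
        if not np.all(np.isfinite(arr)):
            raise MieNumericalError(
                f"non-finite Bessel evaluation at x={x:.6g}, m_t={m_t:.6g} "
                f"(l_max={l_max}); reduce the order or size parameter"
            )

    a = (m_t * psi_mx_tm * dpsi_x - psi_x * dpsi_mx_tm) / (
        m_t * psi_mx_tm * dxi_x - xi_x * dpsi_mx_tm
    )
    b = (psi_mx_te * dpsi_x - m_t * psi_x * dpsi_mx_te) / (
        psi_mx_te * dxi_x - m_t * xi_x * dpsi_mx_te
    )
    return MultipoleCoefficients(
        l_max=l_max, a=a, b=b, x=x, m_t=m_t, m_r=m_r, nu=nu
    )


def scattering_efficiency(
    sphere: AnisotropicSphere,
    wavelengths: np.ndarray,
    n_medium: float = 1.33,
    l_max: Optional[int] = None,
    per_multipole: bool = False,
) -> ScatteringSpectrum:
    """Q_sca(lambda) for a sphere in a host medium.

    Q_sca is the scattering cross-section normalised by the geometric
    cross-section, ``(2/x^2) sum_n (2n+1)(|a_n|^2 + |b_n|^2)``.  With
    ``per_multipole=True`` the individual TE/TM channel contributions are
    stored as well (they sum exactly to the total).
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.size == 0:
        raise ValueError("empty wavelength grid")
    if np.any(np.diff(wavelengths) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")

    # One l_max for the whole grid keeps channel bookkeeping rectangular.
    x_max = 2.0 * math.pi * n_medium / wavelengths[0] * sphere.diameter / 2.0
    lm = l_max if l_max is not None else default_l_max(x_max)

    q = np.empty_like(wavelengths)
    channels: Optional[Dict[Tuple[str, int], np.ndarray]] = None
    if per_multipole:
        channels = {
            (pol, order): np.empty_like(wavelengths)
            for order in range(1, lm + 1)
            for pol in ("TE", "TM")
        }
    orders = np.arange(1, lm + 1)
    weight = 2 * orders + 1
    for i, lam in enumerate(wavelengths):
        coeff = mie_coefficients(sphere, OpticalContext(n_medium, lam), l_max=lm)
        qa = (2.0 / coeff.x**2) * weight * np.abs(coeff.a) ** 2
        qb = (2.0 / coeff.x**2) * weight * np.abs(coeff.b) ** 2
        q[i] = np.sum(qa) + np.sum(qb)
        if channels is not None:
            for j, order in enumerate(orders):
                channels[("TM", int(order))][i] = qa[j]
                channels[("TE", int(order))][i] = qb[j]
    return ScatteringSpectrum(
        wavelengths=wavelengths,
        q_sca=q,
        per_multipole=channels,
        meta={
            "diameter_nm": sphere.diameter,
            "n_t": sphere.n_t,
            "n_r": sphere.n_r,
            "n_medium": n_medium,
            "l_max": lm,
        },
    )


def _pi_tau(l_max: int, mu: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Angular functions pi_n(mu) and tau_n(mu), n = 1..l_max, mu = cos(theta)."""
    mu = np.asarray(mu, dtype=float)
    pi = np.zeros((l_max + 1,) + mu.shape)
    tau = np.zeros((l_max,) + mu.shape)
    pi[1] = 1.0
    for n in range(1, l_max + 1):
        if n >= 2:
            pi[n] = ((2 * n - 1) / (n - 1)) * mu * pi[n - 1] - (n / (n - 1)) * pi[n - 2]
        tau[n - 1] = n * mu * pi[n] - (n + 1) * pi[n - 1]
    return pi[1:], tau


def scattering_amplitudes(
    sphere: AnisotropicSphere,
    ctx: OpticalContext,
    angle: np.ndarray | float,
    l_max: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Complex scattering amplitudes S1, S2 at scattering angle(s) in radians.

    The unpolarised differential cross-section is
    ``(|S1|^2 + |S2|^2) / (2 k^2)``; integrated over solid angle it
    reproduces the scattering cross-section.
    """
    angle_arr = np.atleast_1d(np.asarray(angle, dtype=float))
    if np.any((angle_arr < 0) | (angle_arr > math.pi)):
        raise ValueError("scattering angle must lie in [0, pi]")
    coeff = mie_coefficients(sphere, ctx, l_max=l_max)
    mu = np.cos(angle_arr)
    pi_n, tau_n = _pi_tau(coeff.l_max, mu)
    n = coeff.orders.astype(float)
    w = ((2 * n + 1) / (n * (n + 1)))[:, None]
    a = coeff.a[:, None]
    b = coeff.b[:, None]
    s1 = np.sum(w * (a * pi_n + b * tau_n), axis=0)
    s2 = np.sum(w * (a * tau_n + b * pi_n), axis=0)
    if np.isscalar(angle) or np.ndim(angle) == 0:
        return s1[0], s2[0]
    return s1, s2
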