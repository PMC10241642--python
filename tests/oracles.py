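"""Independent reference implementations used only by the test-suite.

These deliberately take different algorithmic routes from the production
code so that agreement between the two is a meaningful cross-check:

* :func:`bhmie` — isotropic Mie coefficients by the classic logarithmic-
  derivative downward recurrence (Bohren & Huffman appendix-style), versus
  the package's direct fractional-order Bessel evaluation.
* :func:`brute_force_cross_section` — trapezoidal fine-grid quadrature of
  the differential cross-section.
* :func:`smoothing_coefficients` — symbolic (sympy) solve of the cutoff
  smoothing conditions of the soft-core pair potential.
"""

from __future__ import annotations

import math

import numpy as np


def bhmie(x: float, m: float, l_max: int):
    """Isotropic Mie coefficients a_n, b_n for size parameter x, relative index m.

    Logarithmic derivative D_n(mx) by downward recurrence; Riccati--Bessel
    psi/chi of the exterior argument by upward recurrence.  Returns complex
    arrays of length l_max (orders 1..l_max).
    """
    nmx = int(max(l_max, x + 4.05 * x ** (1 / 3) + 2) + 16)
    d = np.zeros(nmx + 1, dtype=complex)
    z = m * x
    for n in range(nmx, 0, -1):
        d[n - 1] = n / z - 1.0 / (d[n] + n / z)

    psi0, psi1 = math.cos(x), math.sin(x)
    chi0, chi1 = -math.sin(x), math.cos(x)
    a = np.zeros(l_max, dtype=complex)
    b = np.zeros(l_max, dtype=complex)
    for n in range(1, l_max + 1):
        psi = (2 * n - 1) / x * psi1 - psi0
        chi = (2 * n - 1) / x * chi1 - chi0
        xi = psi - 1j * chi
        xi1 = psi1 - 1j * chi1
        dn = d[n]
        a[n - 1] = ((dn / m + n / x) * psi - psi1) / ((dn / m + n / x) * xi - xi1)
        b[n - 1] = ((dn * m + n / x) * psi - psi1) / ((dn * m + n / x) * xi - xi1)
        psi0, psi1 = psi1, psi
        chi0, chi1 = chi1, chi
    return a, b


def bhmie_q_sca(x: float, m: float, l_max: int | None = None) -> float:
    if l_max is None:
        l_max = int(math.ceil(x + 4.05 * x ** (1 / 3) + 2)) + 5
    a, b = bhmie(x, m, l_max)
    n = np.arange(1, l_max + 1)
    return float((2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2)))


def bhmie_amplitudes(x: float, m: float, theta: float, l_max: int | None = None):
    """S1, S2 from the oracle coefficients with explicit Legendre-based angular
    functions (scipy-free, direct recurrence)."""
    if l_max is None:
        l_max = int(math.ceil(x + 4.05 * x ** (1 / 3) + 2)) + 5
    a, b = bhmie(x, m, l_max)
    mu = math.cos(theta)
    pi_nm1, pi_n = 0.0, 1.0  # pi_0, pi_1
    s1 = 0j
    s2 = 0j
    for n in range(1, l_max + 1):
        tau_n = n * mu * pi_n - (n + 1) * pi_nm1
        f = (2 * n + 1) / (n * (n + 1))
        s1 += f * (a[n - 1] * pi_n + b[n - 1] * tau_n)
        s2 += f * (a[n - 1] * tau_n + b[n - 1] * pi_n)
        pi_next = ((2 * n + 1) * mu * pi_n - (n + 1) * pi_nm1) / n
        pi_nm1, pi_n = pi_n, pi_next
    return s1, s2


def brute_force_cross_section(s1s2_func, k: float, n_theta: int = 4001) -> float:
    """sigma_sca = 2 pi / (2 k^2) * int (|S1|^2+|S2|^2) sin(theta) dtheta by
    fine trapezoid; independent of any Gauss-Legendre machinery."""
    theta = np.linspace(0.0, math.pi, n_theta)
    s1, s2 = s1s2_func(theta)
    integrand = (np.abs(s1) ** 2 + np.abs(s2) ** 2) * np.sin(theta)
    return float(np.trapezoid(integrand, theta) * math.pi / k**2)


def smoothing_coefficients(xc: float, v0: float = 1.0):
    """C_0, C_1, C_2 of the smoothed 12-0 soft-core potential via sympy.

    Conditions: u(xc) = u'(xc) = u''(xc) = 0 where
    u(x) = v0 (x^-12 - 1) + C0 + C1 x^2 + C2 x^4.
    """
    import sympy as sp

    x, c0, c1, c2 = sp.symbols("x C0 C1 C2", real=True)
    u = v0 * (x**-12 - 1) + c0 + c1 * x**2 + c2 * x**4
    eqs = [
        u.subs(x, xc),
        sp.diff(u, x).subs(x, xc),
        sp.diff(u, x, 2).subs(x, xc),
    ]
    sol = sp.solve(eqs, [c0, c1, c2])
    return float(sol[c0]), float(sol[c1]), float(sol[c2])
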