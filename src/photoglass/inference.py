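"""Tangential-index inference from Mie resonance peak positions.

The tangential refractive index of a spherulitic nanosphere can be read off
from the positions of its transverse-electric Mie resonances: the TE peak
wavelengths red-shift monotonically with ``n_t`` and are independent of the
radial index, so matching observed peak wavelengths against calculated
calibration curves (peak wavelength versus ``n_t`` at fixed diameter and
``n_r``) inverts the measurement.  This module provides the peak finder,
the calibration curves, the inversion, and a generator of synthetic noisy
single-particle spectra with known ground truth for recovery studies.

Peak positions, not full lineshapes, are the observable: the comparison
works at the level of where the resonances sit, so the collection geometry
of the dark-field measurement is not modelled.

Note on geometry: the single-particle measurement is performed on dry,
extracted particles, so the default optical context here is air
(``n_medium=1.0``) with a default diameter of 450 nm.  At that size the TE2
(quadrupole) and TE3 (octupole) channels dominate the visible band and both
peaks fall between 400 and 750 nm — the regime in which TE2/TE3
peak-matching operates.  For substantially smaller spheres (~300 nm) those
resonances move into the ultraviolet and the visible peaks are instead
TE1/TE2; the machinery below is label-aware and handles either case.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from photoglass.mie import AnisotropicSphere, ScatteringSpectrum, scattering_efficiency

__all__ = [
    "ResonancePeak",
    "CalibrationCurve",
    "IndexEstimate",
    "CalibrationRangeError",
    "find_peaks",
    "strongest_peaks",
    "calibration_curve",
    "infer_tangential_index",
    "synth_particle_spectrum",
    "DEFAULT_WAVELENGTHS",
    "DEFAULT_NT_GRID",
]

Label = Tuple[str, int]

DEFAULT_WAVELENGTHS = np.arange(400.0, 900.0 + 0.5, 1.0)
DEFAULT_NT_GRID = np.arange(1.50, 2.1001, 0.01)


class CalibrationRangeError(ValueError):
    """Observed peak wavelength lies outside the calibration curve's range."""


@dataclass(frozen=True)
class ResonancePeak:
    """A local maximum of Q_sca, labelled by its dominant multipole channel."""

    label: Label
    wavelength: float
    prominence: float


@dataclass
class CalibrationCurve:
    """Peak wavelength of one labelled resonance versus tangential index.

    ``peak_wavelengths`` carries NaN where the resonance leaves the analysed
    wavelength window.  Over the valid points the curve is strictly
    increasing (resonances red-shift with index), which makes the inversion
    unique.
    """

    label: Label
    n_t_grid: np.ndarray
    peak_wavelengths: np.ndarray
    n_r: float
    diameter: float
    n_medium: float

    def __post_init__(self) -> None:
        lam = self.peak_wavelengths[self.valid]
        if lam.size >= 2 and np.any(np.diff(lam) <= 0):
            raise ValueError(
                f"calibration curve for {self.label} is not strictly increasing"
            )

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.peak_wavelengths)

    def invert(self, wavelength: float) -> Tuple[float, float, bool]:
        """Return (n_t, residual, at_endpoint) for an observed peak wavelength.

        Monotone (PCHIP) interpolation of the calibration relation followed
        by bisection.  A wavelength at either endpoint of the covered range
        returns the endpoint n_t with ``at_endpoint=True``; outside the
        range a :class:`CalibrationRangeError` is raised.
        """
        nt = self.n_t_grid[self.valid]
        lam = self.peak_wavelengths[self.valid]
        if nt.size < 2:
            raise CalibrationRangeError(
                f"calibration curve for {self.label} has fewer than two valid points"
            )
        if wavelength < lam[0] or wavelength > lam[-1]:
            raise CalibrationRangeError(
                f"observed {self.label[0]}{self.label[1]} peak at "
                f"{wavelength:.1f} nm is outside the calibration range "
                f"[{lam[0]:.1f}, {lam[-1]:.1f}] nm"
            )
        interp = PchipInterpolator(nt, lam)
        if wavelength == lam[0] or wavelength == lam[-1]:
            n_est = float(nt[0] if wavelength == lam[0] else nt[-1])
            return n_est, 0.0, True
        n_est = brentq(lambda n: float(interp(n)) - wavelength, nt[0], nt[-1])
        residual = float(interp(n_est)) - wavelength
        return float(n_est), residual, False


@dataclass
class IndexEstimate:
    """Per-resonance tangential-index estimates and their arithmetic mean."""

    per_resonance: Dict[Label, float]
    average: float
    diagnostics: Dict[Label, float] = field(default_factory=dict)
    endpoint_flags: Dict[Label, bool] = field(default_factory=dict)


def _refine_peak(
    wavelengths: np.ndarray, values: np.ndarray, idx: int, half_window: int
) -> float:
    """Sub-grid peak position by a least-squares parabola around ``idx``.

    With ``half_window=1`` this is the classic three-point quadratic
    interpolation; wider windows trade a little bias (cancelled in
    calibration/observation round trips, which use the same refiner) for
    robustness to measurement noise.
    """
    lo = max(0, idx - half_window)
    hi = min(len(wavelengths), idx + half_window + 1)
    lam = wavelengths[lo:hi]
    val = values[lo:hi]
    if lam.size < 3:
        return float(wavelengths[idx])
    c = np.polyfit(lam - lam.mean(), val, 2)
    if c[0] >= 0:  # degenerate (flat/noisy): keep the grid maximum
        return float(wavelengths[idx])
    pos = -c[1] / (2 * c[0]) + lam.mean()
    return float(np.clip(pos, lam[0], lam[-1]))


def find_peaks(
    spectrum: ScatteringSpectrum,
    min_prominence_frac: float = 0.02,
    refine_half_window: int = 5,
    smooth_window: Optional[int] = None,
) -> List[ResonancePeak]:
    """Locate and label local maxima of a per-multipole scattering spectrum.

    Peaks of total Q_sca with prominence above ``min_prominence_frac`` times
    the spectrum maximum are refined by quadratic interpolation and labelled
    by the multipole channel contributing most at the peak (ties broken
    toward the lower order).  A monotone spectrum yields an empty list.

    For noisy measured spectra pass an odd ``smooth_window`` (grid points):
    the total is then Savitzky--Golay filtered (cubic) before peak finding
    and refinement.  Use the *same* smoothing when building the calibration
    curves so that any smoothing-induced peak shift cancels in the
    inversion.
    """
    if spectrum.per_multipole is None:
        raise ValueError("find_peaks requires a spectrum with per-multipole channels")
    q = spectrum.q_sca
    if smooth_window is not None:
        q = signal.savgol_filter(q, smooth_window, 3)
    prominence = min_prominence_frac * float(q.max()) if q.max() > 0 else None
    idx, props = signal.find_peaks(q, prominence=prominence)
    peaks: List[ResonancePeak] = []
    channels = sorted(spectrum.per_multipole.keys(), key=lambda k: (k[1], k[0]))
    for i, p in zip(idx, props["prominences"]):
        lam = _refine_peak(spectrum.wavelengths, q, int(i), refine_half_window)
        j = int(np.argmin(np.abs(spectrum.wavelengths - lam)))
        contrib = [spectrum.per_multipole[c][j] for c in channels]
        label = channels[int(np.argmax(contrib))]
        peaks.append(ResonancePeak(label=label, wavelength=lam, prominence=float(p)))
    return peaks


def strongest_peaks(peaks: List[ResonancePeak]) -> Dict[Label, float]:
    """Most prominent peak wavelength per label (robust choice under noise)."""
    best: Dict[Label, ResonancePeak] = {}
    for p in peaks:
        if p.label not in best or p.prominence > best[p.label].prominence:
            best[p.label] = p
    return {label: p.wavelength for label, p in best.items()}


def calibration_curve(
    diameter: float = 450.0,
    n_r_fixed: float = 1.50,
    n_t_grid: Optional[Sequence[float]] = None,
    label: Label = ("TE", 2),
    n_medium: float = 1.0,
    wavelengths: Optional[np.ndarray] = None,
    min_prominence_frac: float = 0.02,
    smooth_window: Optional[int] = None,
    refine_half_window: int = 5,
) -> CalibrationCurve:
    """Peak wavelength of one labelled resonance as a function of n_t.

    Grid points where the labelled resonance has no peak inside the
    wavelength window are marked absent (NaN).
    """
    n_t_grid = np.asarray(DEFAULT_NT_GRID if n_t_grid is None else n_t_grid, float)
    if np.any(np.diff(n_t_grid) <= 0):
        raise ValueError("n_t grid must be strictly increasing")
    lams = DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths
    peak_lam = np.full(n_t_grid.shape, np.nan)
    for i, nt in enumerate(n_t_grid):
        sphere = AnisotropicSphere(diameter, float(nt), n_r_fixed)
        spec = scattering_efficiency(sphere, lams, n_medium=n_medium, per_multipole=True)
        found = [
            p
            for p in find_peaks(
                spec,
                min_prominence_frac=min_prominence_frac,
                refine_half_window=refine_half_window,
                smooth_window=smooth_window,
            )
            if p.label == label
        ]
        if found:
            peak_lam[i] = max(found, key=lambda p: p.prominence).wavelength
    return CalibrationCurve(
        label=label,
        n_t_grid=n_t_grid,
        peak_wavelengths=peak_lam,
        n_r=n_r_fixed,
        diameter=diameter,
        n_medium=n_medium,
    )


def infer_tangential_index(
    observed_peaks: Dict[Label, float],
    diameter: float = 450.0,
    n_r_fixed: float = 1.50,
    n_t_grid: Optional[Sequence[float]] = None,
    n_medium: float = 1.0,
    wavelengths: Optional[np.ndarray] = None,
    curves: Optional[Dict[Label, CalibrationCurve]] = None,
) -> IndexEstimate:
    """Invert observed labelled peak wavelengths to tangential indices.

    Each label gets its own calibration curve (precomputed curves can be
    passed via ``curves`` to amortise the cost over many inversions); the
    reported average is the arithmetic mean of the per-resonance estimates.
    Observations at a calibration endpoint are flagged (and warned about);
    observations outside the range raise :class:`CalibrationRangeError`
    naming the label.
    """
    if not observed_peaks:
        raise ValueError("at least one labelled observed peak is required")
    per: Dict[Label, float] = {}
    diag: Dict[Label, float] = {}
    flags: Dict[Label, bool] = {}
    for label, lam_obs in observed_peaks.items():
        if curves is not None and label in curves:
            curve = curves[label]
        else:
            curve = calibration_curve(
                diameter=diameter,
                n_r_fixed=n_r_fixed,
                n_t_grid=n_t_grid,
                label=label,
                n_medium=n_medium,
                wavelengths=wavelengths,
            )
        n_est, residual, at_end = curve.invert(float(lam_obs))
        if at_end:
            warnings.warn(
                f"observed {label[0]}{label[1]} peak sits at the calibration "
                f"endpoint n_t={n_est:.3f}; estimate is a bound, not an interior "
                "solution",
                stacklevel=2,
            )
        per[label] = n_est
        diag[label] = residual
        flags[label] = at_end
    average = float(np.mean(list(per.values())))
    return IndexEstimate(
        per_resonance=per, average=average, diagnostics=diag, endpoint_flags=flags
    )


def synth_particle_spectrum(
    n_t_true: float,
    n_r_true: float,
    diameter: float,
    noise_sd: float,
    seed: int,
    n_medium: float = 1.0,
    wavelengths: Optional[np.ndarray] = None,
) -> ScatteringSpectrum:
    """Model single-particle spectrum plus i.i.d. Gaussian noise.

    Stands in for a dark-field measurement of one nanosphere with known
    ground truth.  ``noise_sd`` is the absolute noise standard deviation in
    Q_sca units (use a fraction of the model peak for relative noise);
    ``noise_sd=0`` returns the model spectrum exactly.  Noise is added to
    the total only — the per-multipole channels stay noiseless and are used
    solely for labelling.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lams = DEFAULT_WAVELENGTHS if wavelengths is None else wavelengths
    sphere = AnisotropicSphere(diameter, n_t_true, n_r_true)
    spec = scattering_efficiency(sphere, lams, n_medium=n_medium, per_multipole=True)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        spec.q_sca = spec.q_sca + rng.normal(0.0, noise_sd, size=spec.q_sca.shape)
    spec.meta.update({"n_t_true": n_t_true, "n_r_true": n_r_true, "noise_sd": noise_sd,
                      "seed": seed})
    return spec
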