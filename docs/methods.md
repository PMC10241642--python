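# Methods

`photoglass` models how a thin, dense, disordered layer of radially
birefringent nanospheres — the kind found in the white chromatophores of
cleaner shrimp, built from spherulitic isoxanthopterin organelles — produces
brilliant broadband whiteness in an aqueous medium.  This note records the
models, the parameters that matter, the numerical choices, and the known
limits of each stage.

## Single-particle optics (`photoglass.mie`)

A spherulite presents a tangential refractive index `n_t` (the high
in-plane index of the stacked molecular sheets, oriented along the sphere
surface) and a radial index `n_r` along the surface normal.  Scattering by
such a radially uniaxial sphere separates into the usual TE/TM partial
waves:

* TE (magnetic-type, `b_n`): identical to the isotropic Mie coefficients at
  relative index `m_t = n_t / n_medium`.  They are **exactly independent of
  `n_r`** — the property that makes the index inference below possible.
* TM (electric-type, `a_n`): the interior Riccati–Bessel function acquires
  the fractional order `nu_n = -1/2 + sqrt(1/4 + n(n+1)(n_t/n_r)^2)`,
  reducing to `n` in the isotropic limit.

Conventions are Bohren–Huffman (`exp(-i omega t)`, outgoing
`xi_n = x h_n^(1)(x)`).  Bessel functions are evaluated directly with
`scipy.special.jv/yv` at (half-)fractional order; for the size parameters
of interest (x ≲ 10) this is accurate to machine precision, which the test
suite pins against an independent logarithmic-derivative implementation at
1e-8 relative.  Non-finite Bessel values (absurd size parameters or orders)
raise `MieNumericalError` rather than propagating silently.  The truncation
default is Wiscombe-style, `ceil(x + 4.05 x^(1/3) + 2)`, floored at 3 so the
quadrupole and octupole channels always exist.  Material dispersion is
ignored: indices are constants per run (the defaults are the DFT-derived
n_t = 1.96, n_r = 1.40, water-like cytoplasm 1.33).

A consequence worth stating plainly: because `nu_n` moves the TM resonances
by tens of nanometres when `n_r` varies over 1.40–1.60, the *total* Q_sca
is only insensitive to `n_r` to within roughly 10–35% (depending on size
and medium), not exactly.  What is exactly `n_r`-independent is the TE
channel set, including the TE2/TE3 peak positions the inference stage uses.

## Index inference (`photoglass.inference`)

The tangential index of a measured particle is read off by matching the
observed TE resonance peak wavelengths against calculated calibration
curves (peak wavelength versus `n_t` at fixed diameter and `n_r`), then
averaging the per-resonance estimates.  Peak positions — not lineshapes —
are the observable, so the dark-field collection geometry is not modelled.

Defaults describe the measurement as performed: a dry extracted particle
(medium 1.0) of 450 nm diameter, for which the TE2/TE3 resonances dominate
the visible band and fall between 400 and 750 nm.  (At ~300 nm the same
resonances sit in the ultraviolet and the visible peaks are TE1/TE2; the
machinery is label-aware and works there too.)  Calibration is built on an
`n_t` grid of 1.50–2.10 (step 0.01) with `n_r` fixed at 1.50; inversion is
monotone PCHIP interpolation plus bisection, with endpoint observations
flagged and out-of-range ones rejected by name.

Peak finding uses `scipy.signal.find_peaks` with a prominence floor,
optional Savitzky–Golay smoothing (cubic; window 31 grid points on the
default 1-nm grid) and least-squares parabolic refinement over ±10 points.
The same smoothing/refinement settings must be used for calibration and for
observation so their (small) systematic peak shifts cancel in the round
trip; with that discipline, noiseless round trips recover `n_t` to better
than 0.005 and 2%-noise spectra to ~0.003 median error.

The synthetic-spectrum generator adds seeded i.i.d. Gaussian noise to the
model Q_sca — it emulates shot-to-shot measurement noise only, not
speckle, background slopes or instrument response, so recovery results
bound only the statistical (not systematic) error of the method.

## Glass generation (`photoglass.glass`)

Packings are grown the way the study's originals were: `N` particles with
clipped log-normal diameters (mean 305 nm; spreads 1/15/31/50 nm for
0.33/5/10/16% polydispersity; hard bounds 100–600 nm, clipped not
resampled) start on a dilute simple-cubic lattice and are quenched by a
Langevin thermostat while the periodic box shrinks.  The pair potential is
the smoothed, purely repulsive "12-0" soft core

    v(x) = v0 (x^-12 - 1) + C0 + C1 x^2 + C2 x^4,   x = r / sigma_ij <= 1.5,

with `C_k` fixed by `v = v' = v'' = 0` at the cutoff, and the nonadditive
mixing rule `sigma_ij = (sigma_i + sigma_j)/2 (1 - 0.01 |sigma_i -
sigma_j|)` evaluated with diameters in units of the mean diameter (literal
nanometre differences would make `sigma_ij` negative for large size
disparities).  The cutoff condition is dimensionless (`r/sigma_ij <= 1.5`)
so the smoothing is well defined per pair.

Reduced units: length = mean diameter, energy = v0 = 1, unit mass,
`kT = 0.05`, damping `gamma = 1`, time step `dt = 0.005`, BAOAB
integration with a linked-cell neighbour search.  The box edge shrinks
linearly over the first 90% of the run (a 4x edge contraction, mirroring
the original 20 um → 5 um squeeze) and is held for the final 10% so the
state relaxes at constant volume.  The final box edge is derived from the
sampled diameters so the target filling fraction is hit exactly.  Noise is
drawn chunk-wise from a seeded `numpy` Generator, making runs bit-for-bit
reproducible for a fixed recipe.

Desk scale: the default is N = 1000 and 30,000 steps (a few tens of
seconds), against the original 5-um, 5e5-step slabs; the recipe scales up
unchanged.  Residual energies at the end of a quench are thermal-scale
(~0.2 v0/particle at 35% fill to ~2.6 at 60%); a guard at 8 v0/particle
catches blow-ups.  Fills are refused above 0.72.

Two properties of this potential matter for interpretation.  First, at
`kT = 0.05` the repulsive shoulder is wide: pairs feel ~kT of energy
already at `r ≈ 1.2 sigma_ij`, so a packing at nominal fill phi is
structurally *denser* than hard spheres at phi — its S(q) first peak is
higher than the Percus–Yevick hard-sphere peak at the same nominal phi
(position matches; amplitude does not).  Second, dense quenches carry many
local close-packed motifs: the mean Steinhardt q6 runs 0.35–0.42 where a
Poisson gas gives 0.28, without any long-range order.  Crystallisation
verdicts therefore use the crystalline-particle fraction (share of
particles with their own q6 > 0.5; glasses < 0.25, crystals ~1) together
with the absence of Bragg-scale S(q) peaks, not the mean q6.

## Structural observables (`photoglass.structure`)

g(r) by periodic minimum-image histogram against ideal-gas shell counts;
S(q) from coordinates on box-commensurate wavevectors (2pi/L integer
triples), shell-averaged, evaluated by separable per-axis phase tensors;
the analytic monodisperse Percus–Yevick S(q) in Wertheim's closed form,
with the exact compressibility value at q = 0 and an explicit
`allow_metastable` flag to continue the closed form from the fluid range
(phi < 0.64) up to 0.72 for filling-fraction sweeps.  Polydispersity is
reported as CV = 100 sd/mean, rounded to two significant figures only at
reporting time.

## Slab reflectance (`photoglass.transport`)

The full-wave (FDTD) stage of the original study is replaced by a
dependent-scattering transport model:

1. `dsigma/dOmega (theta) * S(2 k sin(theta/2))`, number-averaged over the
   size distribution (11 quantile nodes of the clipped log-normal) — the
   decoupling approximation, adequate at CV ≤ 16%;
2. `1/l_s` and `1/l_t` by Gauss–Legendre quadrature in cos(theta)
   (128 nodes, doubled until 1e-4 converged), with
   `rho = phi / <(pi/6) d^3>`;
3. slab diffusion `R = 1 - (l_t + z_e)/(L + 2 z_e)`, `z_e = (2/3) l_t`,
   clamped to [0, 1]; no index-mismatch correction to `z_e` (the
   slab/medium contrast is small).  R_vis is the plain mean of R over
   400–700 nm.

Two host models are exposed.  The **bare** host (`host_model="bare"`, the
default for spectra) embeds the scatterer in the pure medium — the
classic form-factor × structure-factor treatment.  It reproduces
fixed-fill spectra well (structural bumps at the right wavelengths; the
birefringent-vs-isotropic reflectance ratios at 50–60% fill) but contains
*no* optical-crowding mechanism: for 305-nm particles the backscattering
angles sample the rising S(q) peak, so 1/l_t grows monotonically with phi
and no interior optimum can form.  The **Maxwell–Garnett** host
(`host_model="maxwell_garnett"`, the default for filling-fraction sweeps)
embeds the scatterer in the MG effective mixture of medium and
(orientation-averaged) particle permittivity at the assembly's phi; as phi
grows the contrast collapses and the reflectance develops the interior
optimum characteristic of crowding, parameter-free.  Its known bias: it
*over*-suppresses low-contrast particles at high fill (the 1.74-index
isotropic assembly is nearly index-matched at phi = 0.5), so absolute
ratios between variants in that regime are better taken from the bare
model.  Near-field physics is not injected here in either mode; it is
exercised explicitly by the coupling module.

With these defaults the sweep places the isotropic optimum at 25% fill
(against ~30% from full-wave simulation) and keeps the birefringent
assembly within 10% of its maximum reflectance across the entire grid up
to 70% — the crowding-robustness contrast the model exists to show.

## Two-sphere near-field coupling (`photoglass.coupling`)

A discrete-dipole (DDA) calculation: two spheres voxelised on a shared
cubic lattice (pitch ≤ d/12; sphere centres on lattice points, voxel
centres offset by half a pitch so sources and monitors never coincide with
a voxel), per-voxel Clausius–Mossotti polarizability with per-axis
radiative correction — a full tensor `alpha = a_r r^ r^ + a_t (I - r^ r^)`
for the birefringent material, with the centre voxel's undefined radial
direction replaced by the isotropic orientation average.  The coupled
equations `(I - alpha G) P = alpha E_inc` are solved by BiCGStab with
FFT-accelerated Green-tensor convolution (the lattice makes the
interaction block-Toeplitz); relative residual 1e-6.  The monitor reads
|Re(E × H*)|/2 on the axis at the far surface of sphere 2; fields sum the
source dipole and every voxel's electric and magnetic Green contributions.
One wavelength (500 nm) is used: the observable is a single scalar per
distance and the claim is an ordering, not a spectrum.

Validation: zero-contrast voxels yield exactly zero moments and the
analytic free-dipole Poynting value at the monitor; a d ≪ lambda sphere
matches the point-polarizability model within 5%; refining the pitch from
d/12 to d/16 moves monitor values by ~1% (voxelisation convergence is
percent-scale — finer than that is not meaningful for DDA at this pitch).

With a dipole at the centre of sphere 1, the birefringent pair couples one
to two orders of magnitude *less* than either isotropic pair at every
centre-to-centre distance 1–4 d, for both source orientations — the radial
anisotropy scrambles the polarization of the emitted near field.  With the
source at the sphere's edge (any of: on-axis near side, far side,
off-axis), this ordering does not survive in the DDA: an edge dipole is
not symmetrically wrapped by the anisotropy and the birefringent coupling
falls between the two isotropic cases.  The suppression effect, as this
solver resolves it, is specific to emitters embedded deep in the
spherulite.

## Pipeline and formats (`photoglass.io`, CLI)

Packings travel as extended-XYZ text (count; `box_edge_nm`, periodic
flags and a provenance JSON on line 2; `x y z diameter_nm` rows at full
float precision — reads use round-trip float parsing so write→read is
exact).  Spectra and curves are CSV with a leading `wavelength_nm` column
and a JSON sidecar for metadata.  `run_pipeline` chains
packing → structure → reflectance → fill sweep and writes a manifest with
seeds, versions and SHA-256 hashes of every output; all randomness flows
from the config seed, so reruns are byte-identical.  The `photoglass` CLI
exposes each stage (`mie`, `infer-index`, `make-glass`, `structure`,
`reflectance`, `sweep-fill`, `couple`, `fixtures`, `run`) as a thin wrapper
over the library.

## Known limitations

* The transport stage is a scalar radiative-transfer surrogate for
  full-wave simulation: no coherent backscattering, no speckle, no angular
  resolution, no absorption, and crowding enters only through the
  effective-host contrast renormalisation.  Quantitative offsets from
  full-wave results are expected; orderings and optima locations are the
  reliable outputs.
* Birefringence enters the transport model at the form-factor level only;
  its near-field decoupling effect is demonstrated separately by the DDA
  module, not fed back into l_t.
* The soft-core glass at kT = 0.05 is effectively denser than hard spheres
  at the same nominal fill; comparisons with hard-sphere theory (PY) are
  quantitative for peak positions, qualitative for peak heights.
* Constant refractive indices per run; the physical material is dispersive
  near its ultraviolet absorption.
* DDA accuracy at pitch d/12 is percent-scale; absolute Poynting values
  are in arbitrary units and only material-to-material comparisons at
  identical geometry are meaningful.
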