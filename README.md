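# photoglass

Optical modelling of **photonic glasses of birefringent nanospheres** — the
disordered, densely packed, spherulitic isoxanthopterin organelles that make
the white patterns of cleaner shrimp brilliantly reflective from layers only
a few micrometres thick, in water.

Dense particle packings normally scatter *worse* per particle ("optical
crowding": above ~30% filling fraction, near-field coupling between
neighbours erodes reflectance).  The biological particles sidestep this: the
stacked molecular sheets inside each sphere orient their high refractive
index tangentially (n_t ≈ 1.96) and their low index radially (n_r ≈ 1.40),
and this extreme radial birefringence suppresses near-field coupling so the
assembly stays bright almost up to the random-packing limit.  This package
implements, end to end, the computational chain behind that argument:

* **`photoglass.mie`** — Mie scattering for radially anisotropic spheres.
  TE waves see only n_t; TM waves carry a fractional radial order
  `nu_n = -1/2 + sqrt(1/4 + n(n+1)(n_t/n_r)^2)`.  Q_sca, amplitudes
  S1/S2 and per-multipole (TE1, TM1, TE2, …) decomposition.
* **`photoglass.inference`** — tangential-index estimation by matching
  measured TE2/TE3 resonance peak wavelengths to calculated calibration
  curves, plus a seeded generator of noisy synthetic single-particle
  spectra for recovery studies.
* **`photoglass.glass`** — polydisperse photonic-glass packings by a
  Langevin quench of soft spheres (smoothed 12-0 repulsive potential,
  nonadditive mixing, clipped log-normal diameters, linear box squeeze).
* **`photoglass.structure`** — g(r), S(q) from coordinates, the closed-form
  Percus–Yevick hard-sphere S(q), Steinhardt bond order, polydispersity.
* **`photoglass.transport`** — dependent-scattering transport model:
  form factor × S(q) → scattering/transport mean free paths → diffuse slab
  reflectance R(λ) and its 400–700 nm mean R_vis; filling-fraction sweeps
  with a Maxwell–Garnett effective-host option that supplies the crowding
  mechanism.
* **`photoglass.coupling`** — the two-sphere near-field experiment: an
  FFT-accelerated coupled-dipole (DDA) solver with per-voxel *tensor*
  polarizability for the radially anisotropic material; dipole source in
  sphere 1, Poynting monitor at the far edge of sphere 2, swept over
  centre-to-centre distance.

Everything is seeded and text-serialisable (extended-XYZ packings, CSV
spectra, JSON manifests); `docs/methods.md` documents models, defaults and
limitations.

## Worked example

Infer the tangential index of a measured 450-nm dry particle from its two
visible TE resonance peaks:

```sh
$ photoglass infer-index --diameter 450 --nr 1.50 --peaks TE2=654.5,TE3=512.4
TE2: n_t = 1.9601
TE3: n_t = 1.9598
average n_t = 1.9600
```

Both resonances independently report n_t ≈ 1.96 — the tangential index of
the stacked-sheet material — even though the radial index was held at an
(incorrect) 1.50: TE peak positions do not depend on n_r.

Generate a packing and sweep the filling fraction:

```sh
$ photoglass make-glass --fill 0.5 --sigma1 31 --n 1000 --seed 7 --out glass.xyz
wrote glass.xyz (phi = 0.5000)
$ photoglass sweep-fill --out sweep.csv
iso_1.96: argmax phi = 0.25
iso_1.74: argmax phi = 0.20
birefringent: argmax phi = 0.70
```

The isotropic assemblies peak near 20–30% filling and decline beyond it —
optical crowding — while the birefringent assembly keeps climbing: its
visible reflectance stays within 10% of its maximum all the way to 70%
fill.  The same contrast appears in the two-sphere near-field coupling
(`photoglass couple`): with a dipole at the centre of one sphere, the
orientation-averaged Poynting magnitude reaching the far side of its
neighbour is about an order of magnitude smaller for birefringent spheres
(4.1e-14 at contact, arbitrary units) than for isotropic n = 1.74 spheres
(5.7e-13), and smaller still relative to isotropic n = 1.96 (1.4e-12), at
every separation tested.

A full demo pipeline (packing → structure → reflectance → sweep, with a
provenance manifest) is one command:

```sh
photoglass run --outdir demo_run --seed 0
```

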