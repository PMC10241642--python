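"""Photonic-glass generation: Langevin quench of polydisperse soft spheres.

Disordered nanosphere packings are produced the way the originals were
grown in silico: particles with log-normally distributed diameters (clipped
to hard bounds) start on a dilute simple-cubic lattice in a large periodic
box, interact through a smoothed, purely repulsive "12-0" soft-core pair
potential with a nonadditive mixing rule,

    v(r) = v0 [ (sigma_ij / r)^12 - 1 ] + sum_{k=0}^{2} C_k (r/sigma_ij)^{2k},
    sigma_ij = (sigma_i + sigma_j)/2 * (1 - eps |sigma_i - sigma_j|),

and are quenched by a Langevin thermostat at low reduced temperature while
the box edge shrinks linearly to the target filling fraction.  The
smoothing coefficients C_k are fixed by requiring the potential and its
first two derivatives to vanish at the dimensionless cutoff x_c = r/sigma_ij,
so forces are C1-continuous everywhere.

Internally everything runs in reduced units: lengths in units of the mean
diameter mu1, energies in v0, unit particle mass, so the nonadditivity
correction eps |sigma_i - sigma_j| is evaluated with diameters measured in
mu1 (literal nanometre differences would make sigma_ij negative for large
size disparities).  Public inputs and outputs are in nanometres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import numpy as np
from numba import njit

__all__ = [
    "GlassRecipe",
    "ParticleConfiguration",
    "PairPotentialParams",
    "PackingError",
    "lognormal_params",
    "sample_diameters",
    "pair_energy",
    "generate_packing",
    "measure_filling_fraction",
    "potential_energy",
]

# Random sphere packings jam near 0.64; soft cores allow a little more, but
# beyond ~0.72 the quench cannot end in an essentially overlap-free state.
MAX_FILL = 0.72

# A finished quench sits at thermal-scale residual energy (~0.2 v0/particle
# at 35% fill up to ~2.6 at 60% for the default recipe); far above this the
# configuration is strained or the integration has blown up.
ENERGY_TOLERANCE_PER_PARTICLE = 8.0


class PackingError(RuntimeError):
    """Raised when a packing cannot be generated or did not relax."""


def _smoothing_coefficients(cutoff_x: float, v0: float) -> np.ndarray:
    """C_0..C_2 from v(x_c) = v'(x_c) = v''(x_c) = 0 (3x3 linear solve)."""
    xc = float(cutoff_x)
    A = np.array(
        [
            [1.0, xc**2, xc**4],
            [0.0, 2.0 * xc, 4.0 * xc**3],
            [0.0, 2.0, 12.0 * xc**2],
        ]
    )
    rhs = np.array(
        [
            -v0 * (xc**-12 - 1.0),
            12.0 * v0 * xc**-13,
            -156.0 * v0 * xc**-14,
        ]
    )
    return np.linalg.solve(A, rhs)


@dataclass(frozen=True)
class PairPotentialParams:
    """Parameters of the smoothed 12-0 soft-core potential."""

    v0: float = 1.0
    eps_nonadd: float = 0.01
    cutoff_x: float = 1.5
    C: Tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.cutoff_x <= 1.0:
            raise ValueError("cutoff_x must exceed 1 (inside the repulsive core)")
        if self.C is None:
            object.__setattr__(
                self, "C", tuple(_smoothing_coefficients(self.cutoff_x, self.v0))
            )


def lognormal_params(mu1: float, sigma1: float) -> Tuple[float, float]:
    """(mu2, sigma2^2) of the underlying normal of a log-normal size law.

    mu2 = log(mu1^2 / sqrt(mu1^2 + sigma1^2)),  sigma2^2 = log(1 + sigma1^2/mu1^2),
    so that the log-normal has mean mu1 and standard deviation sigma1.
    """
    if mu1 <= 0:
        raise ValueError("mu1 must be positive")
    if sigma1 < 0:
        raise ValueError("sigma1 must be >= 0")
    if sigma1 == 0:
        return math.log(mu1), 0.0
    mu2 = math.log(mu1**2 / math.sqrt(mu1**2 + sigma1**2))
    sigma2_sq = math.log(1.0 + sigma1**2 / mu1**2)
    return mu2, sigma2_sq


@dataclass
class GlassRecipe:
    """Full parameterisation of one packing run.

    Lengths in nm; energies in units of v0; ``kT`` is the reduced Langevin
    temperature.  ``final_box`` is normally derived from the sampled
    diameters so that the target filling fraction is met exactly;
    ``initial_box = box_expansion * final_box`` mirrors the original
    20 um -> 5 um squeeze (a factor of four per edge).  The box shrinks
    linearly in edge length over the first ``squeeze_fraction`` of
    ``quench_steps`` and is held fixed for the remainder so the final state
    relaxes at constant volume.
    """

    mu1: float = 305.0
    sigma1: float = 31.0
    d_min: float = 100.0
    d_max: float = 600.0
    target_fill: float = 0.50
    n_particles: int = 1000
    quench_steps: int = 30_000
    kT: float = 0.05
    v0: float = 1.0
    eps_nonadd: float = 0.01
    cutoff_x: float = 1.5
    dt: float = 0.005
    gamma: float = 1.0
    box_expansion: float = 4.0
    squeeze_fraction: float = 0.9
    seed: int = 0
    initial_box: Optional[float] = None
    final_box: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.d_min < self.mu1 < self.d_max):
            raise ValueError("need 0 < d_min < mu1 < d_max")
        if not (0.0 < self.target_fill < MAX_FILL):
            raise ValueError(
                f"target_fill must lie in (0, {MAX_FILL}) for a random packing"
            )
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if (
            self.initial_box is not None
            and self.final_box is not None
            and self.final_box > self.initial_box
        ):
            raise ValueError("final_box must not exceed initial_box")

    @property
    def potential(self) -> PairPotentialParams:
        return PairPotentialParams(
            v0=self.v0, eps_nonadd=self.eps_nonadd, cutoff_x=self.cutoff_x
        )


@dataclass
class ParticleConfiguration:
    """A periodic cubic box of spheres with per-particle diameters (nm)."""

    box_edge: float
    positions: np.ndarray
    diameters: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.diameters = np.asarray(self.diameters, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if self.diameters.shape[0] != self.positions.shape[0]:
            raise ValueError("diameters and positions disagree on N")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]


def sample_diameters(recipe: GlassRecipe, seed: Optional[int] = None) -> np.ndarray:
    """I.i.d. clipped log-normal diameters (nm), seeded and reproducible.

    Out-of-range draws are clipped to the nearest bound (not resampled), so
    extreme particle sizes are avoided without changing the draw count.
    """
    if seed is None:
        seed = recipe.seed
    if recipe.sigma1 == 0:
        return np.full(recipe.n_particles, recipe.mu1)
    mu2, s2sq = lognormal_params(recipe.mu1, recipe.sigma1)
    rng = np.random.default_rng(seed)
    d = rng.lognormal(mean=mu2, sigma=math.sqrt(s2sq), size=recipe.n_particles)
    return np.clip(d, recipe.d_min, recipe.d_max)


def pair_energy(
    r,
    sigma_i,
    sigma_j,
    params: Optional[PairPotentialParams] = None,
    mu1: float = 305.0,
):
    """Pair energy (v0 units) and force magnitude (v0/nm) at separation r (nm).

    ``sigma_i``/``sigma_j`` are the two diameters in nm; the nonadditive
    mixing rule is evaluated with diameters in units of ``mu1``.  The force
    magnitude is -dv/dr (positive = repulsive).  Zero beyond the cutoff,
    C2-continuous at it.
    """
    if params is None:
        params = PairPotentialParams()
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair separation must be positive")
    si = np.asarray(sigma_i, dtype=float) / mu1
    sj = np.asarray(sigma_j, dtype=float) / mu1
    sij = 0.5 * (si + sj) * (1.0 - params.eps_nonadd * np.abs(si - sj))
    x = (r / mu1) / sij
    c0, c1, c2 = params.C
    inside = x <= params.cutoff_x
    xs = np.where(inside, x, 1.0)  # dummy to avoid overflow warnings
    u = params.v0 * (xs**-12 - 1.0) + c0 + c1 * xs**2 + c2 * xs**4
    dudx = -12.0 * params.v0 * xs**-13 + 2.0 * c1 * xs + 4.0 * c2 * xs**3
    energy = np.where(inside, u, 0.0)
    # dv/dr = (du/dx) / (sigma_ij * mu1)  [per nm]
    force = np.where(inside, -dudx / (sij * mu1), 0.0)
    if energy.ndim == 0:
        return float(energy), float(force)
    return energy, force


@njit(cache=True)
def _forces_cells(pos, sig, L, v0, eps, xc, c0, c1, c2):
    """Forces and potential energy with a linked-cell neighbour search.

    Positions in reduced units inside [0, L); sig are reduced diameters.
    """
    n = pos.shape[0]
    forces = np.zeros((n, 3))
    energy = 0.0
    sig_max = sig.max()
    rcut_max = xc * sig_max
    ncell = int(L / rcut_max)
    if ncell < 3:
        ncell = 1
    if ncell == 1:
        # brute force fallback for tiny/dilute boxes
        for i in range(n):
            for j in range(i + 1, n):
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                dz = pos[i, 2] - pos[j, 2]
                dx -= L * round(dx / L)
                dy -= L * round(dy / L)
                dz -= L * round(dz / L)
                r2 = dx * dx + dy * dy + dz * dz
                sij = 0.5 * (sig[i] + sig[j]) * (1.0 - eps * abs(sig[i] - sig[j]))
                rc = xc * sij
                if r2 < rc * rc:
                    r = math.sqrt(r2)
                    x = r / sij
                    u = v0 * (x**-12 - 1.0) + c0 + c1 * x * x + c2 * x**4
                    dudx = -12.0 * v0 * x**-13 + 2.0 * c1 * x + 4.0 * c2 * x**3
                    energy += u
                    fmag = -dudx / sij  # -dv/dr
                    inv_r = 1.0 / r
                    fx = fmag * dx * inv_r
                    fy = fmag * dy * inv_r
                    fz = fmag * dz * inv_r
                    forces[i, 0] += fx
                    forces[i, 1] += fy
                    forces[i, 2] += fz
                    forces[j, 0] -= fx
                    forces[j, 1] -= fy
                    forces[j, 2] -= fz
        return forces, energy

    cell_size = L / ncell
    head = -np.ones(ncell * ncell * ncell, dtype=np.int64)
    nxt = -np.ones(n, dtype=np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        cz = int(pos[i, 2] / cell_size) % ncell
        c = (cx * ncell + cy) * ncell + cz
        nxt[i] = head[c]
        head[c] = i

    for i in range(n):
        cx = int(pos[i, 0] / cell_size) % ncell
        cy = int(pos[i, 1] / cell_size) % ncell
        cz = int(pos[i, 2] / cell_size) % ncell
        for ox in range(-1, 2):
            for oy in range(-1, 2):
                for oz in range(-1, 2):
                    c = (
                        ((cx + ox) % ncell) * ncell + ((cy + oy) % ncell)
                    ) * ncell + ((cz + oz) % ncell)
                    j = head[c]
                    while j >= 0:
                        if j > i:
                            dx = pos[i, 0] - pos[j, 0]
                            dy = pos[i, 1] - pos[j, 1]
                            dz = pos[i, 2] - pos[j, 2]
                            dx -= L * round(dx / L)
                            dy -= L * round(dy / L)
                            dz -= L * round(dz / L)
                            r2 = dx * dx + dy * dy + dz * dz
                            sij = 0.5 * (sig[i] + sig[j]) * (
                                1.0 - eps * abs(sig[i] - sig[j])
                            )
                            rc = xc * sij
                            if r2 < rc * rc:
                                r = math.sqrt(r2)
                                x = r / sij
                                u = (
                                    v0 * (x**-12 - 1.0)
                                    + c0
                                    + c1 * x * x
                                    + c2 * x**4
                                )
                                dudx = (
                                    -12.0 * v0 * x**-13
                                    + 2.0 * c1 * x
                                    + 4.0 * c2 * x**3
                                )
                                energy += u
                                fmag = -dudx / sij
                                inv_r = 1.0 / r
                                fx = fmag * dx * inv_r
                                fy = fmag * dy * inv_r
                                fz = fmag * dz * inv_r
                                forces[i, 0] += fx
                                forces[i, 1] += fy
                                forces[i, 2] += fz
                                forces[j, 0] -= fx
                                forces[j, 1] -= fy
                                forces[j, 2] -= fz
                        j = nxt[j]
    return forces, energy


@njit(cache=True)
def _baoab_chunk(
    pos, vel, sig, noise, L_sched, v0, eps, xc, c0, c1, c2, dt, gamma, kT
):
    """Integrate one chunk of BAOAB Langevin steps with box rescaling.

    ``L_sched`` holds the box edge at the *end* of each step of the chunk;
    positions are rescaled affinely before each step's force evaluation.
    Returns the potential energy after each step.
    """
    n = pos.shape[0]
    nsteps = noise.shape[0]
    energies = np.empty(nsteps)
    c_damp = math.exp(-gamma * dt)
    c_rand = math.sqrt((1.0 - c_damp * c_damp) * kT)
    L = L_sched[0]
    forces, _ = _forces_cells(pos, sig, L, v0, eps, xc, c0, c1, c2)
    for s in range(nsteps):
        # affine squeeze to this step's box edge
        scale = L_sched[s] / L
        L = L_sched[s]
        if scale != 1.0:
            for i in range(n):
                pos[i, 0] *= scale
                pos[i, 1] *= scale
                pos[i, 2] *= scale
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
            vel[i, 0] = c_damp * vel[i, 0] + c_rand * noise[s, i, 0]
            vel[i, 1] = c_damp * vel[i, 1] + c_rand * noise[s, i, 1]
            vel[i, 2] = c_damp * vel[i, 2] + c_rand * noise[s, i, 2]
            pos[i, 0] += 0.5 * dt * vel[i, 0]
            pos[i, 1] += 0.5 * dt * vel[i, 1]
            pos[i, 2] += 0.5 * dt * vel[i, 2]
            pos[i, 0] %= L
            pos[i, 1] %= L
            pos[i, 2] %= L
        forces, epot = _forces_cells(pos, sig, L, v0, eps, xc, c0, c1, c2)
        for i in range(n):
            vel[i, 0] += 0.5 * dt * forces[i, 0]
            vel[i, 1] += 0.5 * dt * forces[i, 1]
            vel[i, 2] += 0.5 * dt * forces[i, 2]
        energies[s] = epot
    return energies


@njit(cache=True)
def _min_scaled_separation(pos, sig, L, eps):
    """min over pairs of r / sigma_ij (overlap diagnostic)."""
    n = pos.shape[0]
    best = 1.0e30
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx -= L * round(dx / L)
            dy -= L * round(dy / L)
            dz -= L * round(dz / L)
            r = math.sqrt(dx * dx + dy * dy + dz * dz)
            sij = 0.5 * (sig[i] + sig[j]) * (1.0 - eps * abs(sig[i] - sig[j]))
            v = r / sij
            if v < best:
                best = v
    return best


def generate_packing(recipe: GlassRecipe) -> ParticleConfiguration:
    """Run the Langevin quench and return the final configuration.

    The run starts from a simple-cubic lattice in the expanded box, shrinks
    the edge linearly over the squeeze phase and holds it for the remainder.
    Fully seeded: the same recipe reproduces diameters and the initial
    lattice bit-identically, and final positions under fixed integrator
    order.

    Raises
    ------
    PackingError
        If the target fill is infeasible or the final state has not relaxed
        (residual per-particle energy above tolerance).
    """
    if recipe.target_fill >= MAX_FILL:
        raise PackingError(f"target_fill {recipe.target_fill} beyond feasibility")
    diameters_nm = sample_diameters(recipe)
    sig = diameters_nm / recipe.mu1  # reduced diameters
    vol = np.sum(math.pi / 6.0 * diameters_nm**3)
    final_box_nm = (
        recipe.final_box
        if recipe.final_box is not None
        else (vol / recipe.target_fill) ** (1.0 / 3.0)
    )
    initial_box_nm = (
        recipe.initial_box
        if recipe.initial_box is not None
        else recipe.box_expansion * final_box_nm
    )
    fill_check = vol / final_box_nm**3
    if abs(fill_check - recipe.target_fill) > 0.01:
        raise PackingError(
            f"final box gives fill {fill_check:.4f}, not within 0.01 of "
            f"target {recipe.target_fill}"
        )

    L0 = initial_box_nm / recipe.mu1
    L1 = final_box_nm / recipe.mu1
    n = recipe.n_particles

    # simple cubic start
    m = int(math.ceil(n ** (1.0 / 3.0)))
    grid = (np.arange(m) + 0.5) * (L0 / m)
    xx, yy, zz = np.meshgrid(grid, grid, grid, indexing="ij")
    lattice = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)[:n]
    pos = np.ascontiguousarray(lattice)
    vel = np.zeros_like(pos)

    params = recipe.potential
    c0, c1, c2 = params.C

    steps = recipe.quench_steps
    n_squeeze = int(round(recipe.squeeze_fraction * steps))
    edge = np.empty(steps)
    if n_squeeze > 0:
        edge[:n_squeeze] = np.linspace(L0, L1, n_squeeze + 1)[1:]
    edge[n_squeeze:] = L1

    rng = np.random.default_rng(recipe.seed + 1)  # independent of size draws
    chunk = 2000
    energy_trace = []
    for start in range(0, steps, chunk):
        stop = min(start + chunk, steps)
        noise = rng.standard_normal((stop - start, n, 3))
        e = _baoab_chunk(
            pos,
            vel,
            sig,
            noise,
            edge[start:stop],
            recipe.v0,
            recipe.eps_nonadd,
            recipe.cutoff_x,
            c0,
            c1,
            c2,
            recipe.dt,
            recipe.gamma,
            recipe.kT,
        )
        stride = max(1, (stop - start) // 20)
        sub = e[::stride]
        if (len(e) - 1) % stride != 0:
            sub = np.append(sub, e[-1])  # keep the true final energy
        energy_trace.append(sub)
    energy_trace = np.concatenate(energy_trace)

    e_final = energy_trace[-1] / n
    if not np.isfinite(e_final) or e_final > ENERGY_TOLERANCE_PER_PARTICLE:
        raise PackingError(
            f"quench did not relax: final energy/particle {e_final:.3g} "
            f"(tolerance {ENERGY_TOLERANCE_PER_PARTICLE}); energy trace: "
            f"{np.array2string(energy_trace / n, precision=3, threshold=50)}"
        )

    config = ParticleConfiguration(
        box_edge=final_box_nm,
        positions=pos * recipe.mu1,
        diameters=diameters_nm,
        provenance={
            "recipe": asdict(recipe),
            "seed": recipe.seed,
            "steps": steps,
            "energy_per_particle": float(e_final),
            "energy_trace_per_particle": (energy_trace / n).tolist(),
        },
    )
    return config


def measure_filling_fraction(config: ParticleConfiguration) -> float:
    """phi = sum (pi/6) d_i^3 / V (overlaps, if any, are not deducted)."""
    if config.n_particles == 0:
        return 0.0
    return float(
        np.sum(math.pi / 6.0 * config.diameters**3) / config.box_edge**3
    )


def potential_energy(
    config: ParticleConfiguration, recipe: Optional[GlassRecipe] = None
) -> float:
    """Total potential energy (v0 units) of a configuration."""
    if recipe is None:
        recipe = GlassRecipe()
    params = recipe.potential
    c0, c1, c2 = params.C
    _, e = _forces_cells(
        np.ascontiguousarray(config.positions / recipe.mu1),
        config.diameters / recipe.mu1,
        config.box_edge / recipe.mu1,
        recipe.v0,
        recipe.eps_nonadd,
        recipe.cutoff_x,
        c0,
        c1,
        c2,
    )
    return float(e)


def min_scaled_separation(
    config: ParticleConfiguration, eps_nonadd: float = 0.01, mu1: float = 305.0
) -> float:
    """Minimum r/sigma_ij over all pairs — an overlap diagnostic."""
    return float(
        _min_scaled_separation(
            np.ascontiguousarray(config.positions / mu1),
            config.diameters / mu1,
            config.box_edge / mu1,
            eps_nonadd,
        )
    )
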