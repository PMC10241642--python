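"""File formats, run configuration and the end-to-end pipeline.

Packings travel as extended-XYZ text (count line, key=value comment line
with the cubic box edge and periodic flags, then ``x y z diameter_nm`` per
particle); spectra and curves as CSV with a leading ``wavelength_nm``
column.  Pipelines are driven by a JSON-serialisable :class:`RunConfig`
whose global seed feeds every stochastic stage, and every run emits a
provenance manifest (inputs, seeds, package version, output hashes).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd

from photoglass.glass import GlassRecipe, ParticleConfiguration, generate_packing
from photoglass.mie import AnisotropicSphere, ScatteringSpectrum
from photoglass.structure import (
    radial_distribution,
    structure_factor_from_config,
)
from photoglass.transport import (
    AssemblySpec,
    TransportResult,
    fill_fraction_sweep,
    reflectance_spectrum,
)

__all__ = [
    "RunConfig",
    "PackingParseError",
    "read_packing",
    "write_packing",
    "read_spectrum",
    "write_spectrum",
    "run_pipeline",
]

logger = logging.getLogger("photoglass")
if not logger.handlers:  # stage-tagged messages to stderr; data never on this stream
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)


class PackingParseError(ValueError):
    """Malformed extended-XYZ packing file; message names the offending line."""


def write_packing(path: Union[str, Path], config: ParticleConfiguration) -> None:
    """Write a configuration as extended-XYZ at full float precision."""
    path = Path(path)
    prov = json.dumps(config.provenance, separators=(",", ":")) if config.provenance else "{}"
    with path.open("w") as fh:
        fh.write(f"{config.n_particles}\n")
        fh.write(
            f'box_edge_nm={float(config.box_edge)!r} pbc="T T T" '
            f"provenance={json.dumps(prov)}\n"
        )
        for p, d in zip(config.positions, config.diameters):
            fh.write(
                f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r} {float(d)!r}\n"
            )


def read_packing(path: Union[str, Path]) -> ParticleConfiguration:
    """Read an extended-XYZ packing; exact round trip of :func:`write_packing`."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise PackingParseError(f"{path}: empty file (line 1)")
    try:
        n = int(lines[0].strip())
    except ValueError as exc:
        raise PackingParseError(f"{path}: line 1 is not a particle count") from exc
    if len(lines) < 2:
        raise PackingParseError(f"{path}: missing metadata line (line 2)")
    meta_line = lines[1]
    box_edge = None
    provenance: dict = {}
    # key=value tokens; values may be quoted strings
    import shlex

    for token in shlex.split(meta_line):
        if "=" not in token:
            continue
        key, value = token.split("=", 1)
        if key == "box_edge_nm":
            box_edge = float(value)
        elif key == "provenance":
            try:
                provenance = json.loads(value)
                if isinstance(provenance, str):
                    provenance = json.loads(provenance)
            except json.JSONDecodeError:
                provenance = {}
    if box_edge is None:
        raise PackingParseError(f"{path}: line 2 lacks box_edge_nm")
    body = lines[2 : 2 + n]
    if len(body) != n:
        raise PackingParseError(
            f"{path}: particle count mismatch at line {2 + len(body) + 1}: "
            f"header says {n}, found {len(body)} rows"
        )
    pos = np.empty((n, 3))
    dia = np.empty(n)
    for i, line in enumerate(body):
        parts = line.split()
        if len(parts) < 4:
            raise PackingParseError(
                f"{path}: line {i + 3} has {len(parts)} columns, need "
                "x y z diameter_nm"
            )
        pos[i] = [float(parts[0]), float(parts[1]), float(parts[2])]
        dia[i] = float(parts[3])
    return ParticleConfiguration(
        box_edge=box_edge, positions=pos, diameters=dia, provenance=provenance
    )


def write_spectrum(
    path: Union[str, Path],
    wavelengths: np.ndarray,
    columns: Dict[str, np.ndarray],
    meta: Optional[dict] = None,
) -> None:
    """CSV with ``wavelength_nm`` first plus named channels; JSON sidecar for meta."""
    path = Path(path)
    frame = pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, float)})
    for name, values in columns.items():
        frame[name] = np.asarray(values, float)
    frame.to_csv(path, index=False, float_format="%.17g")
    if meta is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, default=str)
        )


def read_spectrum(path: Union[str, Path]) -> pd.DataFrame:
    """Read a spectrum CSV; enforces a strictly increasing wavelength grid."""
    frame = pd.read_csv(path, float_precision="round_trip")
    if frame.columns[0] != "wavelength_nm":
        raise ValueError(f"{path}: first column must be wavelength_nm")
    lam = frame["wavelength_nm"].to_numpy()
    if np.any(np.diff(lam) <= 0):
        raise ValueError(f"{path}: wavelength grid not strictly increasing")
    return frame


def spectrum_to_frame(spectrum: ScatteringSpectrum) -> pd.DataFrame:
    cols = {"wavelength_nm": spectrum.wavelengths, "Q_sca": spectrum.q_sca}
    if spectrum.per_multipole:
        for (pol, order), values in sorted(spectrum.per_multipole.items()):
            cols[f"{pol}{order}"] = values
    return pd.DataFrame(cols)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (JSON-roundtrippable).

    Every stochastic stage derives its seed from ``seed``; rerunning an
    identical config reproduces deterministic outputs byte-identically.
    """

    outdir: Union[str, Path] = "photoglass_run"
    seed: int = 0
    n_particles: int = 500
    target_fill: float = 0.50
    sigma1: float = 31.0
    quench_steps: int = 10_000
    thickness: float = 5000.0
    lambda_min: float = 400.0
    lambda_max: float = 700.0
    lambda_step: float = 10.0
    phi_grid_step: float = 0.05
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Canonical end-to-end flow: packing -> structure -> reflectance -> sweep.

    Writes all stage outputs under ``config.outdir`` and returns the
    provenance manifest (also written as ``manifest.json``).  Stage
    failures propagate with the stage name prepended.
    """
    from photoglass import __version__

    logger.setLevel(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lams = np.arange(config.lambda_min, config.lambda_max + 1e-9, config.lambda_step)
    artifacts: Dict[str, Path] = {}

    stage = "make-glass"
    try:
        logger.info("[%s] N=%d fill=%.2f sigma1=%.1f", stage, config.n_particles,
                    config.target_fill, config.sigma1)
        recipe = GlassRecipe(
            n_particles=config.n_particles,
            target_fill=config.target_fill,
            sigma1=config.sigma1,
            quench_steps=config.quench_steps,
            seed=config.seed,
        )
        packing = generate_packing(recipe)
        artifacts["packing"] = outdir / "packing.xyz"
        write_packing(artifacts["packing"], packing)

        stage = "structure"
        logger.info("[%s] g(r) and S(q)", stage)
        sq = structure_factor_from_config(packing, q_max=0.06)
        gr = radial_distribution(packing, bin_width=10.0)
        artifacts["sq"] = outdir / "structure_factor.csv"
        pd.DataFrame({"q_invnm": sq.q, "S": sq.s}).to_csv(artifacts["sq"], index=False)
        artifacts["gr"] = outdir / "pair_correlation.csv"
        pd.DataFrame({"r_nm": gr.r, "g": gr.g}).to_csv(artifacts["gr"], index=False)

        stage = "reflectance"
        logger.info("[%s] slab L=%.0f nm", stage, config.thickness)
        biref = AnisotropicSphere(305.0, 1.96, 1.40)
        assembly = AssemblySpec(
            particle=biref,
            phi=config.target_fill,
            sigma1=config.sigma1,
            structure=sq,
        )
        tr = reflectance_spectrum(assembly, config.thickness, lams)
        artifacts["reflectance"] = outdir / "reflectance.csv"
        write_spectrum(
            artifacts["reflectance"], tr.wavelengths, {"R": tr.reflectance},
            meta={"R_vis": tr.r_vis, **tr.meta},
        )

        stage = "sweep-fill"
        phis = np.arange(config.phi_grid_step, 0.70 + 1e-9, config.phi_grid_step)
        logger.info("[%s] %d fills x 3 variants", stage, len(phis))
        sweep = fill_fraction_sweep(
            {
                "iso_1.96": AnisotropicSphere.isotropic(305.0, 1.96),
                "iso_1.74": AnisotropicSphere.isotropic(305.0, 1.74),
                "birefringent": biref,
            },
            phis,
            config.thickness,
            lams,
            sigma1=config.sigma1,
        )
        artifacts["sweep"] = outdir / "fill_sweep.csv"
        frame = pd.DataFrame({"phi": phis})
        for name, row in sweep.items():
            frame[name] = row["r_vis"]
        frame.to_csv(artifacts["sweep"], index=False)
    except Exception as exc:  # noqa: BLE001 — annotate with stage and re-raise
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items()},
        "outputs": {name: str(p) for name, p in artifacts.items()},
        "hashes": {name: _hash_file(p) for name, p in artifacts.items()},
        "sweep_argmax": {name: row["argmax_phi"] for name, row in sweep.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", outdir)
    return manifest
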