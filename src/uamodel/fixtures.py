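"""Deterministic synthetic inputs: PMF tables and toy proteins.

The external metadynamics parametrization set is not redistributable, so
tests and demonstrations run on synthetic surface potentials that emulate the
characteristic shape of silver-facet profiles: a steep excluded-volume wall,
adsorption minima at the hydration-layer positions (~0.2 nm, between the two
water adlayers, and ~0.47 nm, outside the second adlayer), an optional
barrier between them, and a smooth decay to exactly zero at the cutoff. All
generators are seeded and reproduce byte-identical output for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BeadRegistry, CGProtein, build_cg_protein
from .potentials import SurfacePMFTable

__all__ = ["SyntheticPMFSpec", "synth_pmf", "toy_protein", "toy_pdb_text"]


@dataclass(frozen=True)
class SyntheticPMFSpec:
    """Parameters of a synthetic bead–surface free-energy profile.

    Depths are in kT (negative = attractive well), locations in nm. The
    default two minima sit at the hydration-shell positions; noise_amplitude
    adds seeded Gaussian noise to the interior of the profile only, keeping
    the zero tail at the cutoff intact.
    """

    bead_name: str = "ALA"
    facet: str = "111"
    well_depths: tuple[float, ...] = (-4.0, -2.0)
    well_locations: tuple[float, ...] = (0.2, 0.47)
    well_width: float = 0.05
    barrier_height: float = 1.0
    barrier_location: float = 0.33
    barrier_width: float = 0.04
    wall_height: float = 50.0
    wall_decay: float = 0.012
    r_c: float = 1.0
    h_min: float = 0.08
    step: float = 0.01
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.well_depths) != len(self.well_locations):
            raise ValueError("one depth per well location required")
        if not (self.h_min < min(self.well_locations, default=self.r_c) < self.r_c):
            raise ValueError("well locations must lie inside (h_min, r_c)")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def synth_pmf(spec: SyntheticPMFSpec) -> SurfacePMFTable:
    """Generate a zero-referenced synthetic PMF table from a spec.

    The profile is wall + Gaussian wells + Gaussian barrier, multiplied by a
    smooth switch that forces exactly zero over the last 0.05 nm before r_c.
    With the default narrow wells, the global minimum of the table recovers
    the deepest specified well depth to better than 0.01 kT.
    """
    h = np.arange(spec.h_min, spec.r_c + 0.5 * spec.step, spec.step)
    h = h[h <= spec.r_c + 1e-12]
    f = spec.wall_height * np.exp(-(h - spec.h_min) / spec.wall_decay)
    for depth, loc in zip(spec.well_depths, spec.well_locations):
        f += depth * np.exp(-0.5 * ((h - loc) / spec.well_width) ** 2)
    if spec.barrier_height:
        f += spec.barrier_height * np.exp(
            -0.5 * ((h - spec.barrier_location) / spec.barrier_width) ** 2
        )
    if spec.noise_amplitude:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_amplitude, h.size)
        noise[h > spec.r_c - 0.3] = 0.0
        f += noise
    # taper smoothly to zero approaching the cutoff
    switch = 1.0 - _smoothstep((h - (spec.r_c - 0.25)) / 0.2)
    f *= switch
    table = SurfacePMFTable(
        bead_name=spec.bead_name,
        facet=spec.facet,
        grid=h,
        values=f,
        r_c=spec.r_c,
    )
    return table.zero_referenced()


def toy_protein(
    n_beads: int,
    geometry: str = "line",
    bead_names: tuple[str, ...] | None = None,
    spacing: float = 0.5,
    seed: int = 0,
    registry: BeadRegistry | None = None,
) -> tuple[CGProtein, str]:
    """Build a small synthetic CG protein and its PDB rendering.

    geometry: 'line' places beads along x at the given spacing, 'dumbbell'
    places two beads spacing apart along z, 'random-coil' is a seeded
    self-avoiding-ish random walk with the given step. The PDB text round-
    trips through build_cg_protein to the same positions within PDB coordinate
    precision (10⁻³ nm is below the 10⁻⁴ nm format resolution).
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    registry = registry or BeadRegistry.default()
    if bead_names is None:
        bead_names = ("ALA",) * n_beads
    if len(bead_names) != n_beads:
        raise ValueError("need one bead name per bead")
    beads = tuple(registry.get(name) for name in bead_names)

    if geometry == "line":
        pos = np.zeros((n_beads, 3))
        pos[:, 0] = spacing * np.arange(n_beads)
    elif geometry == "dumbbell":
        if n_beads != 2:
            raise ValueError("dumbbell geometry requires exactly 2 beads")
        pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, spacing]])
    elif geometry == "random-coil":
        rng = np.random.default_rng(seed)
        steps = rng.normal(size=(n_beads - 1, 3)) if n_beads > 1 else np.zeros((0, 3))
        if n_beads > 1:
            steps /= np.linalg.norm(steps, axis=1, keepdims=True)
        pos = np.vstack([np.zeros(3), np.cumsum(spacing * steps, axis=0)])
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    pos = np.round(pos, 4)  # keep coordinates exactly representable in PDB

    protein = CGProtein(
        beads=beads,
        positions=pos,
        source_id=f"toy-{geometry}-{n_beads}",
        residue_ids=tuple((name, i + 1) for i, name in enumerate(bead_names)),
    )
    return protein, toy_pdb_text(protein)


def toy_pdb_text(protein: CGProtein) -> str:
    """Render a CG protein as a PDB with one side-chain pseudo-atom per residue."""
    lines = []
    for k, bead in enumerate(protein.beads):
        x, y, z = protein.positions[k] * 10.0  # nm -> Angstrom
        resname, resseq = protein.residue_ids[k]
        if len(resname) > 3:
            raise ValueError(
                f"residue name {resname!r} does not fit the PDB resName column"
            )
        name = " CA " if resname.upper() == "GLY" else " CB "
        lines.append(
            f"ATOM  {k + 1:5d} {name} {resname:>3.3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"
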