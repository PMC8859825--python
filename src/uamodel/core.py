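"""Domain types for the coarse-grained rigid-body adsorption model.

A protein is reduced to one bead per residue, placed at the centroid of the
side-chain heavy atoms (Cα for glycine, whose surface energetics are aliased
to alanine because the parametrized potentials describe side-chain analogues
with the backbone replaced by hydrogen). The nanoparticle is a homogeneous
sphere or flat slab with a uniform surface potential taken from the measured
ζ-potential; the solvent enters implicitly through the medium's ionic
strength, dielectric constant and temperature.
"""

from __future__ import annotations

import io as _io
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from Bio.PDB import PDBParser

from . import constants

__all__ = [
    "BeadParams",
    "BeadRegistry",
    "CGProtein",
    "NanoParticle",
    "Medium",
    "MediumDerived",
    "ConfigurationState",
    "build_cg_protein",
    "rotate_protein",
    "rotation_matrix",
    "medium_derived",
]

#: backbone atoms excluded from side-chain centroids
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "OT1", "OT2", "H", "HA"}

#: common PDB residue names mapped onto the force-field bead naming convention
RESIDUE_ALIASES = {
    "HIS": "HSD",  # neutral Nδ-protonated histidine is the pH-7 default
    "HID": "HSD",
    "HIE": "HSE",
    "HIP": "HSP",
    "ASH": "ASPP",
    "GLH": "GLUP",
    "LYN": "LSN",
    "CYX": "CYS",
}


@dataclass(frozen=True)
class BeadParams:
    """Parameters of one coarse-grained bead.

    charge is the net charge in elementary charges at neutral pH, radius the
    effective bead radius in nm used in the dispersion term, material_id a key
    into the dielectric-material database, and pmf_name the bead name under
    which tabulated surface potentials are looked up (equals ``name`` except
    for glycine, which borrows the alanine potential).
    """

    name: str
    charge: float
    radius: float
    material_id: str = "amino_acid"
    pmf_name: str | None = None

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"bead {self.name}: radius must be > 0, got {self.radius}")
        if self.pmf_name is None:
            object.__setattr__(self, "pmf_name", self.name)


class BeadRegistry:
    """Named collection of bead parameters, loadable from a YAML file."""

    def __init__(self, beads: dict[str, BeadParams] | None = None):
        self._beads: dict[str, BeadParams] = dict(beads or {})

    def __contains__(self, name: str) -> bool:
        return self._resolve_name(name) in self._beads

    def __len__(self) -> int:
        return len(self._beads)

    def names(self) -> list[str]:
        return sorted(self._beads)

    def add(self, bead: BeadParams) -> None:
        if bead.name in self._beads:
            raise ValueError(f"duplicate bead name {bead.name!r}")
        self._beads[bead.name] = bead

    @staticmethod
    def _resolve_name(name: str) -> str:
        return RESIDUE_ALIASES.get(name.upper(), name.upper())

    def get(self, name: str) -> BeadParams:
        key = self._resolve_name(name)
        try:
            return self._beads[key]
        except KeyError:
            raise KeyError(
                f"no bead parameters registered for residue {name!r}"
            ) from None

    @classmethod
    def from_yaml(cls, path_or_text) -> "BeadRegistry":
        if hasattr(path_or_text, "read"):
            data = yaml.safe_load(path_or_text)
        else:
            with open(path_or_text) as fh:
                data = yaml.safe_load(fh)
        reg = cls()
        for name, entry in data["beads"].items():
            reg.add(
                BeadParams(
                    name=name,
                    charge=float(entry["charge"]),
                    radius=float(entry["radius"]),
                    material_id=entry.get("material_id", "amino_acid"),
                    pmf_name=entry.get("pmf_name"),
                )
            )
        return reg

    def to_yaml(self, path) -> None:
        data = {
            "beads": {
                b.name: {
                    "charge": b.charge,
                    "radius": b.radius,
                    "material_id": b.material_id,
                    **({"pmf_name": b.pmf_name} if b.pmf_name != b.name else {}),
                }
                for b in self._beads.values()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def default(cls) -> "BeadRegistry":
        from .io import packaged_data_path

        return cls.from_yaml(packaged_data_path("beads.yaml"))


@dataclass(frozen=True)
class CGProtein:
    """Rigid one-bead-per-residue protein.

    positions is an (n, 3) array in nm; residue_ids carry the original
    (residue name, sequence number) for contact reporting.
    """

    beads: tuple[BeadParams, ...]
    positions: np.ndarray
    source_id: str = "unnamed"
    residue_ids: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (n, 3) array")
        if len(self.beads) != pos.shape[0]:
            raise ValueError("bead list and position array length mismatch")
        if not np.all(np.isfinite(pos)):
            raise ValueError("bead positions must be finite")
        object.__setattr__(self, "positions", pos)
        if not self.residue_ids:
            object.__setattr__(
                self,
                "residue_ids",
                tuple((b.name, i + 1) for i, b in enumerate(self.beads)),
            )

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def com(self) -> np.ndarray:
        """Unweighted centre of the bead positions, nm."""
        return self.positions.mean(axis=0)

    def rotated(self, theta: float, phi: float) -> "CGProtein":
        return rotate_protein(self, theta, phi)


def rotation_matrix(theta: float, phi: float) -> np.ndarray:
    """Body rotation R_z(phi) @ R_y(theta) used for orientation sampling."""
    ct, st = math.cos(theta), math.sin(theta)
    cp, sp = math.cos(phi), math.sin(phi)
    ry = np.array([[ct, 0.0, st], [0.0, 1.0, 0.0], [-st, 0.0, ct]])
    rz = np.array([[cp, -sp, 0.0], [sp, cp, 0.0], [0.0, 0.0, 1.0]])
    return rz @ ry


def rotate_protein(protein: CGProtein, theta: float, phi: float) -> CGProtein:
    """Rigidly rotate the protein about its COM by R_z(phi) R_y(theta).

    Angles are wrapped into canonical ranges; the COM and all pairwise bead
    distances are preserved to machine precision.
    """
    theta = float(theta) % (2.0 * math.pi)
    if theta > math.pi:  # fold (theta, phi) onto the canonical hemisphere
        theta = 2.0 * math.pi - theta
        phi = phi + math.pi
    phi = float(phi) % (2.0 * math.pi)
    com = protein.com
    rot = rotation_matrix(theta, phi)
    new_pos = (protein.positions - com) @ rot.T + com
    return replace(protein, positions=new_pos)


@dataclass(frozen=True)
class NanoParticle:
    """Nanoparticle geometry, surface potential and facet composition.

    surface_potential is φ_s in mV (taken from the measured ζ-potential);
    facet_weights maps crystallographic facet labels ('100', '110', '111') to
    weights summing to 1.
    """

    shape: str = "sphere"
    radius: float | None = None
    surface_potential: float = 0.0
    facet_weights: dict[str, float] = field(
        default_factory=lambda: {"100": 1 / 3, "110": 1 / 3, "111": 1 / 3}
    )
    material_id: str = "silver"

    def __post_init__(self):
        if self.shape not in ("sphere", "slab"):
            raise ValueError(f"shape must be 'sphere' or 'slab', got {self.shape!r}")
        if self.shape == "sphere":
            if self.radius is None or not self.radius > 0:
                raise ValueError("sphere nanoparticle requires radius > 0")
        total = sum(self.facet_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"facet weights must sum to 1, got {total}")


@dataclass(frozen=True)
class Medium:
    """Implicit aqueous medium: ionic species, dielectric constant, T."""

    species: tuple[tuple[float, int], ...] = ((0.15, 1), (0.15, -1))
    dielectric: float = 78.4
    temperature: float = constants.DEFAULT_TEMPERATURE

    def __post_init__(self):
        if self.dielectric <= 1:
            raise ValueError("dielectric must exceed 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        species = tuple((float(c), int(z)) for c, z in self.species)
        for c, _ in species:
            if c < 0:
                raise ValueError("concentrations must be non-negative")
        net = sum(c * z for c, z in species)
        scale = sum(c * abs(z) for c, z in species)
        if scale > 0 and abs(net) > 1e-6 * scale:
            raise ValueError(f"medium is not electroneutral (net {net} mol e/L)")
        object.__setattr__(self, "species", species)


@dataclass(frozen=True)
class MediumDerived:
    ionic_strength: float  # mol/L
    bjerrum_length: float  # nm
    inverse_debye_length: float  # 1/nm
    unscreened: bool = False


def medium_derived(medium: Medium) -> MediumDerived:
    """Ionic strength, Bjerrum length and inverse Debye length of a medium.

    I = ½ Σ c_i z_i² (mol/L); λ_B = e²/(4π ε₀ ε k_BT) (nm);
    κ = sqrt(8π λ_B N_A 10³ I) (1/nm). A salt-free medium gives κ = 0 with an
    ``unscreened`` flag and a warning rather than an exception.
    """
    ionic = 0.5 * sum(c * z * z for c, z in medium.species)
    lb = constants.bjerrum_length_nm(medium.dielectric, medium.temperature)
    if ionic == 0.0:
        warnings.warn("medium has zero ionic strength: electrostatics unscreened")
        return MediumDerived(0.0, lb, 0.0, unscreened=True)
    # number density per nm^3 = NA * 1e3 * I / 1e27
    kappa = math.sqrt(8.0 * math.pi * lb * constants.N_AVOGADRO * 1e3 * ionic * 1e-27)
    return MediumDerived(ionic, lb, kappa)


@dataclass(frozen=True)
class ConfigurationState:
    """One rigid-body configuration: orientation angles and COM separation.

    z is the COM–COM distance for a spherical particle and the COM height
    above the surface plane for a slab, both in nm.
    """

    theta: float
    phi: float
    z: float

    def __post_init__(self):
        if not (0.0 <= self.theta <= math.pi + 1e-12):
            raise ValueError("theta must lie in [0, pi]")
        if not (0.0 <= self.phi < 2.0 * math.pi + 1e-12):
            raise ValueError("phi must lie in [0, 2 pi)")
        if self.z < 0:
            raise ValueError("z must be non-negative")


def _sidechain_centroid(residue) -> np.ndarray | None:
    coords = []
    for atom in residue.get_atoms():
        if atom.element == "H":
            continue
        if atom.get_name() in _BACKBONE_ATOMS:
            continue
        coords.append(atom.get_coord())
    if not coords:
        return None
    return np.mean(coords, axis=0)


def build_cg_protein(
    pdb_record: str, registry: BeadRegistry, source_id: str | None = None
) -> CGProtein:
    """Coarse-grain a PDB structure into one bead per residue.

    Bead positions are the centroids of side-chain heavy atoms (glycine falls
    back to Cα); bead parameters come from the registry, with glycine bound to
    the alanine surface potential. Only the first MODEL is read and PDB Å
    coordinates are converted to nm. Unknown residues or residues missing all
    side-chain heavy atoms raise with the offending residue named.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(source_id or "protein", _io.StringIO(pdb_record))
    try:
        model = next(structure.get_models())
    except StopIteration:
        raise ValueError("PDB record contains no models") from None

    beads: list[BeadParams] = []
    positions: list[np.ndarray] = []
    residue_ids: list[tuple[str, int]] = []
    for chain in model:
        for residue in chain:
            hetflag, resseq, _ = residue.get_id()
            if hetflag.strip() and residue.get_resname() not in registry:
                continue  # water / unparametrized heteroatoms
            resname = residue.get_resname().strip()
            if resname in ("HOH", "WAT"):
                continue
            if resname not in registry:
                raise KeyError(
                    f"no bead parameters registered for residue {resname!r} "
                    f"(chain {chain.id}, residue {resseq})"
                )
            bead = registry.get(resname)
            if resname.upper() == "GLY":
                # glycine has no side chain: Cα position, alanine energetics
                if "CA" not in residue:
                    raise ValueError(f"residue {resname} {resseq} lacks a Cα atom")
                centroid = np.asarray(residue["CA"].get_coord())
            else:
                centroid = _sidechain_centroid(residue)
                if centroid is None:
                    raise ValueError(
                        f"residue {resname} {resseq} has no side-chain heavy atoms"
                    )
            beads.append(bead)
            positions.append(centroid * 0.1)  # Å -> nm
            residue_ids.append((resname, int(resseq)))

    if not beads:
        raise ValueError("PDB record contains no parametrizable residues")
    return CGProtein(
        beads=tuple(beads),
        positions=np.array(positions),
        source_id=source_id or structure.id,
        residue_ids=tuple(residue_ids),
    )
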