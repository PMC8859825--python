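"""Rigid-body orientation/distance scanning and adsorption-energy averaging.

For every orientation (θ_k, φ_l) of the protein the total bead-additive
energy U(z) is scanned along the COM separation z, from the first sterically
allowed contact out to where the interaction has decayed. The Boltzmann-
weighted mean of U over that interval (with measure dz for a slab, z²dz for a
sphere) gives the per-orientation energy E(θ_k, φ_l); averaging over
orientations arithmetically yields E_ads^A and canonically (with Boltzmann
factors P_kl) yields E_ads^B ≤ E_ads^A. The global minimum over (θ, φ, z)
defines the lowest-energy pose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize_scalar

from . import constants
from .core import CGProtein, ConfigurationState, Medium, NanoParticle, rotate_protein
from .potentials import (
    WALL_CAP_KT,
    DEFAULT_SLAB_THICKNESS,
    HamakerConstant,
    SurfacePMFTable,
    bead_energy,
)

__all__ = [
    "OrientationGrid",
    "PotentialSet",
    "AdsorptionMap",
    "AdsorptionSummary",
    "configuration_energy",
    "mean_energy_over_z",
    "orientation_map",
    "average_simple",
    "average_boltzmann",
    "facet_average",
    "lowest_energy_pose",
    "summarize",
]


@dataclass(frozen=True)
class OrientationGrid:
    """Regular (θ, φ) grid over the orientation sphere with sin θ weights."""

    theta_values: np.ndarray
    phi_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta_values", np.asarray(self.theta_values, float))
        object.__setattr__(self, "phi_values", np.asarray(self.phi_values, float))
        if self.theta_values.size == 0 or self.phi_values.size == 0:
            raise ValueError("orientation grid must be non-empty")

    @classmethod
    def from_degrees(cls, step: float = 5.0) -> "OrientationGrid":
        thetas = np.deg2rad(np.arange(0.0, 180.0 + 0.5 * step, step))
        phis = np.deg2rad(np.arange(0.0, 360.0, step))
        return cls(thetas, phis)

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta_values.size, self.phi_values.size

    def weights(self) -> np.ndarray:
        """Solid-angle weights ∝ sin θ, normalized to sum to 1."""
        w_theta = np.sin(self.theta_values)
        if np.all(w_theta == 0.0):  # degenerate grid (poles only): fall back to uniform
            w_theta = np.ones_like(w_theta)
        w = np.outer(w_theta, np.ones(self.phi_values.size))
        return w / w.sum()


@dataclass
class PotentialSet:
    """All interaction inputs for one particle facet.

    tables maps PMF bead names to their tabulated surface potential for this
    facet; hamaker maps the same names to the bead's Hamaker constant with the
    particle core across the solvent.
    """

    np_spec: NanoParticle
    medium: Medium
    tables: dict[str, SurfacePMFTable]
    hamaker: dict[str, HamakerConstant]
    facet: str = ""
    slab_thickness: float = DEFAULT_SLAB_THICKNESS

    def bead_table(self, pmf_name: str) -> SurfacePMFTable:
        try:
            return self.tables[pmf_name]
        except KeyError:
            raise KeyError(
                f"no PMF table for bead {pmf_name!r} on facet {self.facet or '?'}"
            ) from None

    def bead_hamaker(self, pmf_name: str) -> HamakerConstant:
        return self.hamaker.get(pmf_name, HamakerConstant(0.0))

    @property
    def contact_h(self) -> float:
        """Smallest sampled separation across the tables (steric contact)."""
        return max(t.h_min for t in self.tables.values()) if self.tables else 0.1

    @property
    def max_r_c(self) -> float:
        return max(t.r_c for t in self.tables.values()) if self.tables else 1.2


def _bead_separations(
    positions: np.ndarray, np_spec: NanoParticle, z: float
) -> np.ndarray:
    """Surface separation h_i of each bead for the protein COM placed at z."""
    shifted = positions + np.array([0.0, 0.0, z])
    if np_spec.shape == "slab":
        return shifted[:, 2]
    return np.linalg.norm(shifted, axis=1) - np_spec.radius


def configuration_energy(
    protein: CGProtein,
    potset: PotentialSet,
    state: ConfigurationState,
) -> float:
    """Total protein–particle energy U(z, θ, φ) in kT for one configuration.

    The protein is rotated to (θ, φ) about its COM, the COM is placed at
    separation z from the particle COM (sphere) or surface plane (slab), and
    bead energies are summed pairwise-additively. Beads driven into steric
    overlap contribute the capped wall energy instead of raising.
    """
    rotated = rotate_protein(protein, state.theta, state.phi)
    rel = rotated.positions - rotated.com
    hs = _bead_separations(rel, potset.np_spec, state.z)
    total = 0.0
    for bead, h in zip(rotated.beads, hs):
        if h <= 1e-9:
            total += WALL_CAP_KT
            continue
        table = potset.bead_table(bead.pmf_name)
        A = potset.bead_hamaker(bead.pmf_name)
        total += bead_energy(
            bead, table, A, potset.np_spec, potset.medium, float(h),
            slab_thickness=potset.slab_thickness,
        )
    return total


def mean_energy_over_z(
    u_profile,
    geometry: str,
    z_lo: float,
    z_hi: float,
    rel_tol: float = 1e-4,
    decay_tol: float = 0.05,
) -> tuple[float, float]:
    """Boltzmann-weighted mean of U(z) over [z_lo, z_hi], with interval length a.

    E = ∫ U e^{-U} w dz / ∫ e^{-U} w dz with geometric measure w = 1 for a
    slab and w = z² for a sphere (volume element about the particle centre).
    Trapezoidal quadrature on a uniformly refined grid, doubled until the
    result is converged to rel_tol.
    """
    if geometry not in ("slab", "sphere"):
        raise ValueError("geometry must be 'slab' or 'sphere'")
    if z_hi <= z_lo:
        raise ValueError("empty z interval")
    u_end = float(np.asarray(u_profile(z_hi)).reshape(-1)[0])
    if abs(u_end) > decay_tol:
        raise ValueError(
            f"profile has not decayed at z = {z_hi} nm "
            f"(|U| = {abs(u_end):.3g} kT): interval too short"
        )

    prev = None
    n = 512
    while True:
        z = np.linspace(z_lo, z_hi, n + 1)
        try:
            u = np.asarray(u_profile(z), dtype=float)
            if u.shape != z.shape:
                raise TypeError
        except (TypeError, ValueError):  # scalar-only callable
            u = np.array([float(u_profile(zi)) for zi in z])
        w = z**2 if geometry == "sphere" else np.ones_like(z)
        boltz = np.exp(-np.clip(u, -700.0, 700.0))
        denom = np.trapezoid(w * boltz, z)
        numer = np.trapezoid(w * boltz * u, z)
        est = numer / denom
        if prev is not None and abs(est - prev) <= max(rel_tol * abs(est), 1e-9):
            return float(est), float(z_hi - z_lo)
        if n >= 65536:
            return float(est), float(z_hi - z_lo)
        prev = est
        n *= 2


def _z_contact(rel: np.ndarray, np_spec: NanoParticle, h_contact: float) -> float:
    """Smallest COM separation z at which every bead keeps h_i >= h_contact."""
    if np_spec.shape == "slab":
        return h_contact - float(rel[:, 2].min())
    R = np_spec.radius + h_contact
    rho2 = rel[:, 0] ** 2 + rel[:, 1] ** 2
    reach = R * R - rho2
    cand = -rel[:, 2] + np.sqrt(np.maximum(reach, 0.0))
    cand = cand[reach > 0.0]
    return float(cand.max()) if cand.size else R


@dataclass
class AdsorptionMap:
    """Per-orientation mean energies E(θ_k, φ_l) on an orientation grid.

    E is in kT; a holds the z-integration interval length per orientation
    (nm); U_min / z_min record the depth and location of the z-profile
    minimum, used for pose extraction.
    """

    grid: OrientationGrid
    E: np.ndarray
    a: np.ndarray
    U_min: np.ndarray | None = None
    z_min: np.ndarray | None = None
    facet: str = ""
    np_spec: NanoParticle | None = None
    protein_id: str = ""

    def __post_init__(self):
        self.E = np.asarray(self.E, float)
        self.a = np.asarray(self.a, float)
        if self.E.shape != self.grid.shape:
            raise ValueError("E matrix shape does not match the orientation grid")
        if not np.all(np.isfinite(self.E)):
            raise ValueError("E contains non-finite entries")
        if np.any(self.a <= 0):
            raise ValueError("integration intervals must be positive")


@dataclass(frozen=True)
class AdsorptionSummary:
    E_ads_A: float  # kT
    E_ads_B: float  # kT
    best_pose: tuple[float, float, float]  # theta, phi, z
    P: np.ndarray = field(repr=False, default=None)

    @property
    def E_ads_A_kj_mol(self) -> float:
        return self.E_ads_A * constants.KT_KJ_PER_MOL_300

    @property
    def E_ads_B_kj_mol(self) -> float:
        return self.E_ads_B * constants.KT_KJ_PER_MOL_300


def _z_profile(
    protein_rel: np.ndarray,
    beads,
    potset: PotentialSet,
    z_lo: float,
    z_span: float,
    z_step: float,
    decay_tol: float,
):
    """Sample U(z) from z_lo outward, extending until |U| < decay_tol."""

    def u_at(z: float) -> float:
        hs = _bead_separations(protein_rel, potset.np_spec, z)
        total = 0.0
        for bead, h in zip(beads, hs):
            if h <= 1e-9:
                total += WALL_CAP_KT
                continue
            total += bead_energy(
                bead,
                potset.bead_table(bead.pmf_name),
                potset.bead_hamaker(bead.pmf_name),
                potset.np_spec,
                potset.medium,
                float(h),
                slab_thickness=potset.slab_thickness,
            )
        return total

    z_hi = z_lo + z_span
    for _ in range(8):
        if abs(u_at(z_hi)) < decay_tol:
            break
        z_hi += z_span
    zs = np.arange(z_lo, z_hi + 0.5 * z_step, z_step)
    us = np.array([u_at(z) for z in zs])
    return zs, us, u_at


def orientation_map(
    protein: CGProtein,
    potset: PotentialSet,
    grid: OrientationGrid | None = None,
    h_contact: float | None = None,
    z_step: float = 0.01,
    decay_tol: float = 1e-3,
) -> AdsorptionMap:
    """Scan all grid orientations and compute E(θ_k, φ_l) by z-averaging.

    For each orientation the z interval runs from the first non-overlapping
    contact (all beads at h ≥ h_contact, default the smallest tabulated
    separation) to the distance where the total interaction has decayed below
    decay_tol kT. Deterministic for fixed inputs.
    """
    grid = grid or OrientationGrid.from_degrees(5.0)
    h_contact = potset.contact_h if h_contact is None else h_contact
    geometry = potset.np_spec.shape
    n_t, n_p = grid.shape
    E = np.zeros((n_t, n_p))
    a = np.zeros((n_t, n_p))
    U_min = np.zeros((n_t, n_p))
    z_min = np.zeros((n_t, n_p))
    z_span = potset.max_r_c + 1.0
    for i, theta in enumerate(grid.theta_values):
        for j, phi in enumerate(grid.phi_values):
            rotated = rotate_protein(protein, float(theta), float(phi))
            rel = rotated.positions - rotated.com
            z_lo = max(_z_contact(rel, potset.np_spec, h_contact), 1e-6)
            zs, us, u_at = _z_profile(
                rel, rotated.beads, potset, z_lo, z_span, z_step, decay_tol
            )
            interp = PchipInterpolator(zs, us)
            E[i, j], a[i, j] = mean_energy_over_z(
                interp, geometry, float(zs[0]), float(zs[-1]), decay_tol=10 * decay_tol
            )
            k = int(np.argmin(us))
            lo, hi = zs[max(k - 1, 0)], zs[min(k + 1, zs.size - 1)]
            if hi > lo:
                res = minimize_scalar(interp, bounds=(lo, hi), method="bounded")
                U_min[i, j], z_min[i, j] = float(res.fun), float(res.x)
            else:
                U_min[i, j], z_min[i, j] = float(us[k]), float(zs[k])
    return AdsorptionMap(
        grid=grid,
        E=E,
        a=a,
        U_min=U_min,
        z_min=z_min,
        facet=potset.facet,
        np_spec=potset.np_spec,
        protein_id=protein.source_id,
    )


def average_simple(amap: AdsorptionMap) -> float:
    """Solid-angle-weighted arithmetic mean adsorption energy E_ads^A, kT."""
    w = amap.grid.weights()
    return float(np.sum(w * amap.E))


def average_boltzmann(
    amap: AdsorptionMap, weighted: bool = True
) -> tuple[float, np.ndarray]:
    """Canonical (Boltzmann-weighted) mean adsorption energy E_ads^B, kT.

    P_kl ∝ w_kl exp(−E_kl) with solid-angle weights w (set weighted=False to
    drop them); overflow is guarded by shifting by the minimum energy. Always
    E_ads^B ≤ E_ads^A.
    """
    w = amap.grid.weights() if weighted else np.full(amap.E.shape, 1.0 / amap.E.size)
    logp = -(amap.E - amap.E.min())
    P = w * np.exp(logp)
    P /= P.sum()
    return float(np.sum(P * amap.E)), P


def facet_average(per_facet: dict[str, float], weights: dict[str, float] | None = None) -> float:
    """Weighted arithmetic mean over facets (equal weights by default)."""
    if not per_facet:
        raise ValueError("no facet values supplied")
    if weights is None:
        weights = {f: 1.0 / len(per_facet) for f in per_facet}
    total_w = 0.0
    total = 0.0
    for facet, wt in weights.items():
        if wt == 0.0:
            continue
        if facet not in per_facet:
            raise KeyError(f"missing energy for facet {facet!r} with weight {wt}")
        total += wt * per_facet[facet]
        total_w += wt
    return total / total_w


def lowest_energy_pose(
    amap: AdsorptionMap,
    protein: CGProtein,
    potset: PotentialSet,
) -> tuple[ConfigurationState, str, list[tuple[str, int, float]]]:
    """Global-minimum pose, its PDB rendering, and the surface contact list.

    The (θ, φ) grid node with the deepest z-profile minimum (ties broken by
    ascending θ index, then φ index) is refined by a bounded 1-D minimization
    in z. Contacts are residues with h_i < 0.5 nm, sorted by h_i. The PDB text
    is deterministic for identical inputs.
    """
    if amap.U_min is None:
        raise ValueError("map does not carry z-profile minima")
    flat = np.round(amap.U_min, 12)
    i, j = np.unravel_index(int(np.argmin(flat, axis=None)), flat.shape)
    theta = float(amap.grid.theta_values[i])
    phi = float(amap.grid.phi_values[j])
    rotated = rotate_protein(protein, theta, phi)
    rel = rotated.positions - rotated.com
    z0 = float(amap.z_min[i, j])

    def u_at(z: float) -> float:
        return configuration_energy(protein, potset, ConfigurationState(theta, phi, z))

    lo = max(z0 - 0.1, _z_contact(rel, potset.np_spec, potset.contact_h))
    res = minimize_scalar(u_at, bounds=(lo, z0 + 0.1), method="bounded")
    z_best = float(res.x)
    state = ConfigurationState(theta, phi, z_best)

    placed = rel + np.array([0.0, 0.0, z_best])
    hs = _bead_separations(rel, potset.np_spec, z_best)
    contacts = sorted(
        (
            (rotated.residue_ids[k][0], rotated.residue_ids[k][1], float(hs[k]))
            for k in range(rotated.n_beads)
            if hs[k] < 0.5
        ),
        key=lambda c: c[2],
    )
    pdb_text = _pose_pdb(rotated, placed, potset.np_spec)
    return state, pdb_text, contacts


def _pose_pdb(protein: CGProtein, placed_nm: np.ndarray, np_spec: NanoParticle) -> str:
    lines = []
    lines.append("REMARK   1 COARSE-GRAINED ADSORPTION POSE (ONE BEAD PER RESIDUE)")
    if np_spec.shape == "sphere":
        lines.append(
            f"REMARK   1 NANOPARTICLE SPHERE AT ORIGIN, RADIUS {np_spec.radius:8.3f} NM"
        )
        lines.append(
            "HETATM    1 AG    NP Z   1    "
            f"{0.0:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00          AG"
        )
    else:
        lines.append("REMARK   1 NANOPARTICLE SLAB SURFACE AT Z = 0")
    serial = 2
    for k, bead in enumerate(protein.beads):
        x, y, z = placed_nm[k] * 10.0  # nm -> Angstrom
        name = " CA " if bead.name == "GLY" else " CB "
        resname, resseq = protein.residue_ids[k]
        lines.append(
            f"ATOM  {serial:5d} {name} {resname:>3.3s} A{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def summarize(amap: AdsorptionMap, protein: CGProtein, potset: PotentialSet) -> AdsorptionSummary:
    """Bundle the two averages and the refined best pose for one facet map."""
    e_a = average_simple(amap)
    e_b, P = average_boltzmann(amap)
    state, _, _ = lowest_energy_pose(amap, protein, potset)
    return AdsorptionSummary(
        E_ads_A=e_a, E_ads_B=e_b, best_pose=(state.theta, state.phi, state.z), P=P
    )
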