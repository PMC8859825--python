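"""Per-bead energy terms of the coarse-grained adsorption model.

The nonbonded bead–nanoparticle interaction is split at a cutoff r_c
(1.0–1.2 nm): below it, a tabulated potential of mean force (PMF) from
atomistic metadynamics describes the bead–surface interaction, supplemented
by a dispersion correction for the particle core material that the thin MD
slab did not represent; beyond it, the full core dispersion (Hamaker)
potential applies. Screened Debye–Hückel electrostatics driven by the
particle's ζ-potential act at all separations. All energies are returned in
units of k_BT at the medium temperature; separations h are surface separation
distances (NP surface to bead centre) in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator

from . import constants
from .core import BeadParams, Medium, NanoParticle, medium_derived

__all__ = [
    "SurfacePMFTable",
    "HamakerMaterial",
    "HamakerConstant",
    "hamaker_constant",
    "core_potential",
    "core_correction",
    "surface_pmf_eval",
    "electrostatic_energy",
    "bead_energy",
    "WALL_CAP_KT",
    "DEFAULT_SLAB_THICKNESS",
]

#: hard-core extrapolation cap for separations below the sampled grid, kT
WALL_CAP_KT = 50.0

#: thickness (nm) of the metal slab used in the PMF parametrization runs
DEFAULT_SLAB_THICKNESS = 1.1

#: tolerance on the PMF value at the cutoff after zero-referencing, kT
ZERO_REF_TOL = 0.25


@dataclass
class SurfacePMFTable:
    """Tabulated short-range bead–surface free energy for one facet.

    grid holds strictly increasing surface separation distances in nm spanning
    [h_min, r_c]; values are free energies in kT, expected to vanish at the
    cutoff r_c (zero-referenced against the bulk).
    """

    bead_name: str
    facet: str
    grid: np.ndarray
    values: np.ndarray
    r_c: float = 1.0
    zero_ref: bool = False
    _interp: PchipInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.ndim != 1 or self.grid.size < 4:
            raise ValueError("PMF grid needs at least 4 points")
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        diffs = np.diff(self.grid)
        if np.any(diffs <= 0):
            i = int(np.argmax(diffs <= 0))
            raise ValueError(f"PMF grid not strictly increasing at index {i + 1}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PMF values contain non-finite entries")
        if self.zero_ref and abs(self.value_at_cutoff()) > ZERO_REF_TOL:
            raise ValueError(
                f"table {self.bead_name}/{self.facet} marked zero-referenced but "
                f"|F(r_c)| = {abs(self.value_at_cutoff()):.3f} kT"
            )

    @property
    def h_min(self) -> float:
        return float(self.grid[0])

    def value_at_cutoff(self) -> float:
        return float(np.interp(min(self.r_c, self.grid[-1]), self.grid, self.values))

    def zero_referenced(self, window: float = 0.1) -> "SurfacePMFTable":
        """Shift values so the mean over the last `window` nm before r_c is 0."""
        hi = min(self.r_c, float(self.grid[-1]))
        mask = self.grid >= hi - window
        shift = float(self.values[mask].mean())
        return SurfacePMFTable(
            bead_name=self.bead_name,
            facet=self.facet,
            grid=self.grid.copy(),
            values=self.values - shift,
            r_c=self.r_c,
            zero_ref=True,
        )

    def interpolator(self) -> PchipInterpolator:
        if self._interp is None:
            self._interp = PchipInterpolator(self.grid, self.values, extrapolate=False)
        return self._interp


def surface_pmf_eval(table: SurfacePMFTable, h) -> float | np.ndarray:
    """Evaluate the tabulated surface potential at separation h (nm), in kT.

    Beyond r_c the potential is exactly 0. Inside the grid a shape-preserving
    cubic (PCHIP) passes through the nodes. Below the first node the value is
    linearly extrapolated with the slope at h_min and capped at the hard-core
    wall energy, keeping Boltzmann integrals finite for overlapping states.
    """
    h_arr = np.atleast_1d(np.asarray(h, dtype=float))
    out = np.zeros_like(h_arr)
    interp = table.interpolator()
    inside = (h_arr >= table.h_min) & (h_arr < table.r_c)
    if np.any(inside):
        vals = interp(np.minimum(h_arr[inside], table.grid[-1]))
        out[inside] = np.nan_to_num(vals, nan=float(table.values[-1]))
    below = h_arr < table.h_min
    if np.any(below):
        slope = float(interp.derivative()(table.h_min))
        extrap = table.values[0] + slope * (h_arr[below] - table.h_min)
        out[below] = np.minimum(extrap, WALL_CAP_KT)
    return out if np.ndim(h) else float(out[0])


@dataclass(frozen=True)
class HamakerMaterial:
    """Dielectric response data of one phase for Lifshitz theory.

    For dielectrics, frequency is the dominant electronic absorption frequency
    (Hz); for conductors it is the plasma frequency and the static dielectric
    constant is irrelevant (taken as infinite in the zero-frequency term).
    """

    material_id: str
    dielectric: float | None
    refractive_index: float
    kind: str = "dielectric"
    frequency: float = 3.0e15

    def __post_init__(self):
        if self.kind not in ("dielectric", "conducting"):
            raise ValueError(f"unknown material kind {self.kind!r}")
        if self.kind == "dielectric" and (self.dielectric is None or self.dielectric <= 0):
            raise ValueError(f"material {self.material_id}: dielectric constant required")
        if self.refractive_index < 1 and self.kind == "dielectric":
            raise ValueError("refractive index must be >= 1")
        if self.frequency <= 0:
            raise ValueError("characteristic frequency must be positive")

    def eps_imag_axis(self, nu: float) -> float:
        """Single-oscillator dielectric response eps(i nu) on the imaginary axis."""
        if self.kind == "conducting":
            return 1.0 + (self.frequency / nu) ** 2
        return 1.0 + (self.refractive_index**2 - 1.0) / (1.0 + (nu / self.frequency) ** 2)


@dataclass(frozen=True)
class HamakerConstant:
    """Hamaker constant A_132 for bead (1) and particle (2) across solvent (3)."""

    A: float  # J
    materials: tuple[str, str, str] = ("", "", "")

    def in_kT(self, temperature: float) -> float:
        return self.A / constants.kT_joule(temperature)


def _delta0(m: HamakerMaterial, solvent: HamakerMaterial) -> float:
    if m.kind == "conducting":
        return 1.0  # eps -> infinity limit
    return (m.dielectric - solvent.dielectric) / (m.dielectric + solvent.dielectric)


def _dispersion_closed_form(
    m1: HamakerMaterial, m2: HamakerMaterial, m3: HamakerMaterial
) -> float:
    """Two-term Lifshitz dispersion contribution for three dielectrics.

    Uses the standard n²-based approximation; when absorption frequencies
    differ, each (j, solvent) pair gets the geometric-mean frequency and the
    generalized unlike-frequency combination rule, which reduces to the
    familiar single-frequency formula when all frequencies coincide.
    """
    n1s, n2s, n3s = (m.refractive_index**2 for m in (m1, m2, m3))
    s1 = math.sqrt(n1s + n3s)
    s2 = math.sqrt(n2s + n3s)
    nu1 = math.sqrt(m1.frequency * m3.frequency)
    nu2 = math.sqrt(m2.frequency * m3.frequency)
    num = 3.0 * constants.PLANCK_H * nu1 * nu2 * (n1s - n3s) * (n2s - n3s)
    den = 8.0 * math.sqrt(2.0) * s1 * s2 * (nu1 * s1 + nu2 * s2)
    return num / den


def _dispersion_integral(
    m1: HamakerMaterial, m2: HamakerMaterial, m3: HamakerMaterial
) -> float:
    """Dispersion contribution by quadrature of the Lifshitz frequency integral.

    A_disp = (3h/4π) ∫ Δ13(iν) Δ23(iν) dν with single-oscillator spectra; used
    whenever a conducting phase is involved, for which no two-term closed form
    exists. Substituting ν = ν_ref tan(u) maps the half-line onto (0, π/2).
    """

    nu_ref = min(m1.frequency, m2.frequency)

    def integrand(u: float) -> float:
        nu = nu_ref * math.tan(u)
        if nu <= 0.0:
            return 0.0
        jac = nu_ref / math.cos(u) ** 2
        e1 = m1.eps_imag_axis(nu)
        e2 = m2.eps_imag_axis(nu)
        e3 = m3.eps_imag_axis(nu)
        d13 = (e1 - e3) / (e1 + e3)
        d23 = (e2 - e3) / (e2 + e3)
        return d13 * d23 * jac

    val, _ = quad(integrand, 0.0, math.pi / 2.0, limit=200)
    return 3.0 * constants.PLANCK_H / (4.0 * math.pi) * val


def hamaker_constant(
    m1: HamakerMaterial,
    m2: HamakerMaterial,
    m3: HamakerMaterial,
    temperature: float = constants.DEFAULT_TEMPERATURE,
) -> HamakerConstant:
    """Hamaker constant A_132 from dielectric data of the three phases.

    Zero-frequency (static) term (3/4) k_BT Δ13(0) Δ23(0) plus the dispersion
    term: the standard two-term Lifshitz approximation when both non-solvent
    phases are dielectric, or numerical integration of the single-oscillator
    Lifshitz spectral integral when one of them conducts (plasma-frequency
    response). Symmetric under exchange of materials 1 and 2.
    """
    if m3.kind == "conducting":
        raise ValueError("a conducting solvent is not supported")
    zero_term = 0.75 * constants.kT_joule(temperature) * _delta0(m1, m3) * _delta0(m2, m3)
    if m1.kind == "dielectric" and m2.kind == "dielectric":
        disp = _dispersion_closed_form(m1, m2, m3)
    else:
        disp = _dispersion_integral(m1, m2, m3)
    return HamakerConstant(
        A=zero_term + disp,
        materials=(m1.material_id, m2.material_id, m3.material_id),
    )


def _u_sphere_halfspace(A: float, radius: float, gap: float) -> float:
    """Hamaker energy (J) of a sphere at surface gap `gap` from a half-space."""
    r, h = radius, gap
    return -(A / 6.0) * (r / h + r / (h + 2.0 * r) + math.log(h / (h + 2.0 * r)))


def _u_two_spheres(A: float, r1: float, r2: float, gap: float) -> float:
    """Hamaker energy (J) of two spheres with surface-to-surface gap `gap`."""
    d = r1 + r2 + gap
    d2 = d * d
    s_plus = (r1 + r2) ** 2
    s_minus = (r1 - r2) ** 2
    return -(A / 6.0) * (
        2.0 * r1 * r2 / (d2 - s_plus)
        + 2.0 * r1 * r2 / (d2 - s_minus)
        + math.log((d2 - s_plus) / (d2 - s_minus))
    )


def core_potential(
    A: HamakerConstant,
    np_spec: NanoParticle,
    bead_radius: float,
    h: float,
    temperature: float = constants.DEFAULT_TEMPERATURE,
) -> float:
    """Long-range core dispersion energy at surface separation h (nm), in kT.

    A slab particle uses the sphere–half-space closed form for the bead sphere
    at surface gap h; a spherical particle uses the two-sphere form with
    centre separation R_NP + R_bead + h. Attractive (≤ 0) for A > 0, vanishing
    at large h.
    """
    if h <= 0:
        raise ValueError("core potential requires h > 0 (overlap handled by the PMF wall)")
    if bead_radius <= 0:
        raise ValueError("bead radius must be positive")
    if np_spec.shape == "slab":
        u_j = _u_sphere_halfspace(A.A, bead_radius, h)
    else:
        u_j = _u_two_spheres(A.A, np_spec.radius, bead_radius, h)
    return u_j / constants.kT_joule(temperature)


def _u_bead_slab(A: float, bead_radius: float, gap: float, thickness: float) -> float:
    """Hamaker energy (J) of a bead sphere with an infinite slab of finite thickness."""
    return _u_sphere_halfspace(A, bead_radius, gap) - _u_sphere_halfspace(
        A, bead_radius, gap + thickness
    )


def core_correction(
    A: HamakerConstant,
    np_spec: NanoParticle,
    bead_radius: float,
    h: float,
    r_c: float,
    slab_thickness: float = DEFAULT_SLAB_THICKNESS,
    temperature: float = constants.DEFAULT_TEMPERATURE,
) -> float:
    """Core-material dispersion not already encoded in the PMF, in kT.

    The PMF was parametrized against a thin slab of the particle material, so
    inside the cutoff the tabulated term already contains the dispersion with
    that slab. The correction is the dispersion energy of the bead with the
    full particle body minus that with the parametrization slab held at the
    same surface gap; it tends to the full core potential as the slab
    thickness tends to zero.
    """
    if not (0.0 < h < r_c):
        raise ValueError("core correction applies only for 0 < h < r_c")
    if slab_thickness < 0:
        raise ValueError("slab thickness must be non-negative")
    u_full = core_potential(A, np_spec, bead_radius, h, temperature)
    u_slab = _u_bead_slab(A.A, bead_radius, h, slab_thickness) / constants.kT_joule(
        temperature
    )
    return u_full - u_slab


def electrostatic_energy(
    bead: BeadParams,
    np_spec: NanoParticle,
    medium: Medium,
    h: float,
) -> float:
    """Screened electrostatic bead–particle energy at separation h (nm), kT.

    Linearized Poisson–Boltzmann surface-potential decay
    U = z e φ_s exp(−κ h) R_NP/(R_NP + h), with the curvature factor equal to
    1 for a slab. φ_s is the ζ-potential in mV.
    """
    if h < 0:
        raise ValueError("h must be non-negative")
    if bead.charge == 0.0 or np_spec.surface_potential == 0.0:
        return 0.0
    derived = medium_derived(medium)
    phi_joule = constants.E_CHARGE * np_spec.surface_potential * 1e-3
    u0 = bead.charge * phi_joule / constants.kT_joule(medium.temperature)
    curvature = 1.0
    if np_spec.shape == "sphere":
        curvature = np_spec.radius / (np_spec.radius + h)
    return u0 * math.exp(-derived.inverse_debye_length * h) * curvature


def bead_energy(
    bead: BeadParams,
    table: SurfacePMFTable,
    A: HamakerConstant,
    np_spec: NanoParticle,
    medium: Medium,
    h: float,
    slab_thickness: float = DEFAULT_SLAB_THICKNESS,
) -> float:
    """Total bead–particle energy at surface separation h (nm), in kT.

    Inside the cutoff: tabulated PMF + core correction + electrostatics.
    At or beyond the cutoff: core dispersion + electrostatics. Zero
    referencing of the table keeps the two branches continuous at r_c to
    within the referencing tolerance.
    """
    T = medium.temperature
    r_c = table.r_c
    if h <= 0:
        return WALL_CAP_KT
    if h < r_c:
        u = surface_pmf_eval(table, h)
        u += core_correction(A, np_spec, bead.radius, h, r_c, slab_thickness, T)
    else:
        u = core_potential(A, np_spec, bead.radius, h, T)
    return u + electrostatic_energy(bead, np_spec, medium, h)
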