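"""Orientation scanning, z-averaging and adsorption-energy averaging."""

import math

import numpy as np
import pytest
from scipy.interpolate import PchipInterpolator

import uamodel as ua
from uamodel.core import ConfigurationState
from uamodel.fixtures import SyntheticPMFSpec, synth_pmf, toy_protein

from conftest import flat_zero_table, make_potset


def zero_potset(np_spec, medium, bead_names=("ALA",)):
    tables = {n: flat_zero_table(n) for n in bead_names}
    return make_potset(np_spec, medium, tables)


def dumbbell_potset(np_spec, medium):
    """Two-bead probe: weakly repelled ALA head, strongly bound TRP head."""
    tables = {
        "ALA": synth_pmf(SyntheticPMFSpec(bead_name="ALA",
                                          well_depths=(2.0, 1.0))),
        "TRP": synth_pmf(SyntheticPMFSpec(bead_name="TRP",
                                          well_depths=(-8.0, -3.0))),
    }
    return make_potset(np_spec, medium, tables)


class TestConfigurationEnergy:
    def test_single_bead_equals_bead_energy(self, registry, slab_np, medium,
                                            ala_table, single_ala):
        potset = make_potset(slab_np, medium, {"ALA": ala_table})
        for z in (0.2, 0.5, 1.4):
            got = ua.configuration_energy(single_ala, potset,
                                          ConfigurationState(0.0, 0.0, z))
            expected = ua.bead_energy(registry.get("ALA"), ala_table,
                                      ua.HamakerConstant(0.0), slab_np,
                                      medium, z)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_potentials_zero_everywhere(self, registry, medium, slab_np):
        protein, _ = toy_protein(4, "random-coil", seed=5, registry=registry)
        neutral = ua.NanoParticle(shape="slab", radius=None,
                                  surface_potential=0.0,
                                  facet_weights={"111": 1.0})
        potset = zero_potset(neutral, medium)
        for theta, phi, z in [(0, 0, 3.0), (1.0, 2.0, 2.0), (2.5, 0.4, 4.0)]:
            assert ua.configuration_energy(
                protein, potset, ConfigurationState(theta, phi, z)) == 0.0

    def test_matches_brute_force_bead_loop(self, registry, medium, sphere_np):
        """Independent per-bead loop with an explicit rotation matrix."""
        names = ("ALA", "LYS", "TRP", "ASP", "SER")
        protein, _ = toy_protein(5, "random-coil", bead_names=names, seed=9,
                                 registry=registry)
        tables = {n: synth_pmf(SyntheticPMFSpec(
            bead_name=n, well_depths=(-1.0 - i, -0.4), seed=i))
            for i, n in enumerate(names)}
        hamaker = {n: ua.HamakerConstant((1 + i) * 4e-21)
                   for i, n in enumerate(names)}
        potset = make_potset(sphere_np, medium, tables, hamaker)
        theta, phi, z = 1.1, 0.7, sphere_np.radius + 1.0
        got = ua.configuration_energy(protein, potset,
                                      ConfigurationState(theta, phi, z))
        ct, st, cp, sp = (math.cos(theta), math.sin(theta),
                          math.cos(phi), math.sin(phi))
        rot = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]]) @ \
            np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
        com = protein.positions.mean(axis=0)
        expected = 0.0
        for bead, pos in zip(protein.beads, protein.positions):
            rel = rot @ (pos - com)
            h = math.sqrt(rel[0]**2 + rel[1]**2 + (rel[2] + z)**2) - sphere_np.radius
            expected += ua.bead_energy(bead, tables[bead.name],
                                       hamaker[bead.name], sphere_np, medium, h)
        assert got == pytest.approx(expected, abs=1e-3)


class TestMeanEnergyOverZ:
    def test_zero_field(self):
        E, a = ua.mean_energy_over_z(lambda z: np.zeros_like(np.asarray(z, float)),
                                     "slab", 0.0, 2.0)
        assert E == 0.0
        assert a == 2.0

    def test_square_well_closed_form(self):
        """Slab measure: E = 0.2*(-5)e^5 / (0.2 e^5 + 1.8)."""

        def well(z):
            z = np.asarray(z, float)
            return np.where((z >= 0.5) & (z <= 0.7), -5.0, 0.0)

        E, _ = ua.mean_energy_over_z(well, "slab", 0.0, 2.0, rel_tol=1e-6)
        expected = 0.2 * (-5.0) * math.exp(5.0) / (0.2 * math.exp(5.0) + 1.8)
        assert E == pytest.approx(expected, abs=5e-3)

    def test_sphere_measure_against_fixed_grid_quadrature(self):
        """z^2 dz measure vs an independent fine trapezoidal quadrature."""
        rng = np.random.default_rng(3)
        locs = rng.uniform(10.3, 11.5, 4)
        amps = rng.uniform(-3.0, -0.5, 4)

        def profile(z):
            z = np.asarray(z, float)
            u = np.zeros_like(z)
            for a, l in zip(amps, locs):
                u += a * np.exp(-0.5 * ((z - l) / 0.1) ** 2)
            return u

        E, _ = ua.mean_energy_over_z(profile, "sphere", 10.2, 13.0, rel_tol=1e-6)
        z = np.linspace(10.2, 13.0, 200001)
        u = profile(z)
        w = z**2 * np.exp(-u)
        oracle = np.trapezoid(w * u, z) / np.trapezoid(w, z)
        assert E == pytest.approx(oracle, abs=1e-3)

    def test_undivided_profile_rejected(self):
        with pytest.raises(ValueError, match="interval too short"):
            ua.mean_energy_over_z(lambda z: np.full_like(np.asarray(z, float), -2.0),
                                  "slab", 0.0, 1.0)


class TestOrientationMap:
    def test_zero_potentials_zero_map(self, registry, medium):
        neutral = ua.NanoParticle(shape="slab", radius=None,
                                  surface_potential=0.0,
                                  facet_weights={"111": 1.0})
        protein, _ = toy_protein(3, "line", registry=registry)
        potset = zero_potset(neutral, medium)
        amap = ua.orientation_map(protein, potset,
                                  ua.OrientationGrid.from_degrees(45))
        assert np.all(amap.E == 0.0)
        assert ua.average_simple(amap) == 0.0
        assert ua.average_boltzmann(amap)[0] == 0.0

    def test_single_bead_orientation_independent(self, medium, slab_np,
                                                 ala_table, single_ala):
        potset = make_potset(slab_np, medium, {"ALA": ala_table})
        amap = ua.orientation_map(single_ala, potset,
                                  ua.OrientationGrid.from_degrees(45))
        assert np.ptp(amap.E) < 1e-12

    def test_single_bead_recovers_direct_boltzmann_integral(
            self, registry, medium, slab_np, ala_table, single_ala):
        """Engine E_ads on a slab equals the 1-D Boltzmann integral of the PMF."""
        potset = make_potset(slab_np, medium, {"ALA": ala_table})
        amap = ua.orientation_map(single_ala, potset,
                                  ua.OrientationGrid.from_degrees(90))
        bead = registry.get("ALA")

        def u(z):
            z = np.atleast_1d(z)
            return np.array([ua.bead_energy(bead, ala_table,
                                            ua.HamakerConstant(0.0), slab_np,
                                            medium, max(zi, 1e-9))
                             for zi in z])

        z_lo, z_hi = ala_table.h_min, float(amap.a[0, 0]) + ala_table.h_min
        oracle, _ = ua.mean_energy_over_z(u, "slab", z_lo, z_hi, rel_tol=1e-7)
        assert ua.average_simple(amap) == pytest.approx(oracle, abs=1e-3)

    def test_dumbbell_binding_bead_faces_surface(self, registry, medium, slab_np):
        """The z-profile minimum is deepest when the bound head points down."""
        protein, _ = toy_protein(2, "dumbbell", bead_names=("ALA", "TRP"),
                                 spacing=1.0, registry=registry)
        potset = dumbbell_potset(slab_np, medium)
        grid = ua.OrientationGrid.from_degrees(30)
        amap = ua.orientation_map(protein, potset, grid)
        i, j = np.unravel_index(int(np.argmin(amap.U_min)), amap.U_min.shape)
        # theta > pi/2 tilts the TRP head (initially at +z) toward the surface
        assert amap.grid.theta_values[i] > math.pi / 2
        # brute-force oracle over the same coarse orientations
        brute = np.zeros(grid.shape)
        for a, theta in enumerate(grid.theta_values):
            for b, phi in enumerate(grid.phi_values):
                zs = np.arange(1.1 * 0.08, 2.5, 0.005)
                us = [ua.configuration_energy(
                    protein, potset, ConfigurationState(theta, phi, z))
                    for z in zs]
                brute[a, b] = min(us)
        bi, bj = np.unravel_index(int(np.argmin(brute)), brute.shape)
        assert grid.theta_values[bi] > math.pi / 2
        assert brute.min() == pytest.approx(float(amap.U_min.min()), abs=0.02)

    def test_matches_independent_nested_loop_reference(self, registry, medium,
                                                       slab_np):
        """Map energies for a 3-bead probe vs a from-scratch reference."""
        names = ("ALA", "LYS", "SER")
        protein, _ = toy_protein(3, "line", bead_names=names, spacing=0.6,
                                 registry=registry)
        tables = {n: synth_pmf(SyntheticPMFSpec(bead_name=n,
                                                well_depths=(-1.5, -0.5)))
                  for n in names}
        potset = make_potset(slab_np, medium, tables)
        grid = ua.OrientationGrid(np.array([0.0, math.pi / 2]),
                                  np.array([0.0, math.pi]))
        amap = ua.orientation_map(protein, potset, grid)
        h_contact = max(t.h_min for t in tables.values())
        for i, theta in enumerate(grid.theta_values):
            for j, phi in enumerate(grid.phi_values):
                ct, st = math.cos(theta), math.sin(theta)
                cp, sp = math.cos(phi), math.sin(phi)
                rot = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]]) @ \
                    np.array([[ct, 0, st], [0, 1, 0], [-st, 0, ct]])
                com = protein.positions.mean(axis=0)
                rel = (protein.positions - com) @ rot.T
                z_lo = h_contact - rel[:, 2].min()
                z_hi = z_lo + float(amap.a[i, j])
                zs = np.linspace(z_lo, z_hi, 2001)
                us = np.zeros_like(zs)
                for bead, r in zip(protein.beads, rel):
                    hs = r[2] + zs
                    us += [ua.bead_energy(bead, tables[bead.name],
                                          ua.HamakerConstant(0.0), slab_np,
                                          medium, float(h)) for h in hs]
                boltz = np.exp(-us)
                ref = np.trapezoid(us * boltz, zs) / np.trapezoid(boltz, zs)
                assert amap.E[i, j] == pytest.approx(ref, abs=1e-3)

    def test_grid_refinement_converged(self, registry, medium, slab_np):
        """Halving the grid spacing changes E_ads^B by < 2%."""
        protein, _ = toy_protein(2, "dumbbell", bead_names=("ALA", "TRP"),
                                 spacing=1.0, registry=registry)
        potset = dumbbell_potset(slab_np, medium)
        e_coarse, _ = ua.average_boltzmann(
            ua.orientation_map(protein, potset, ua.OrientationGrid.from_degrees(30)))
        e_fine, _ = ua.average_boltzmann(
            ua.orientation_map(protein, potset, ua.OrientationGrid.from_degrees(15)))
        assert e_fine == pytest.approx(e_coarse, rel=0.02)


class TestAveraging:
    @staticmethod
    def _map_from_E(E, thetas=None, phis=None):
        E = np.asarray(E, float)
        thetas = np.asarray(thetas if thetas is not None
                            else np.linspace(0.3, math.pi - 0.3, E.shape[0]))
        phis = np.asarray(phis if phis is not None
                          else np.linspace(0.0, 2 * math.pi, E.shape[1],
                                           endpoint=False))
        grid = ua.OrientationGrid(thetas, phis)
        return ua.AdsorptionMap(grid=grid, E=E, a=np.ones_like(E))

    def test_constant_map(self):
        amap = self._map_from_E(np.full((4, 6), -3.2))
        assert ua.average_simple(amap) == pytest.approx(-3.2)
        e_b, P = ua.average_boltzmann(amap)
        assert e_b == pytest.approx(-3.2)
        np.testing.assert_allclose(P, amap.grid.weights())

    def test_two_orientation_closed_forms(self):
        """Equal weights on {0, -10 kT}: mean -5; canonical -10 e^10/(1+e^10)."""
        amap = self._map_from_E(np.array([[0.0, -10.0]]),
                                thetas=[math.pi / 2], phis=[0.0, math.pi])
        assert ua.average_simple(amap) == pytest.approx(-5.0)
        e_b, P = ua.average_boltzmann(amap)
        expected = -10.0 * math.exp(10.0) / (1.0 + math.exp(10.0))
        assert e_b == pytest.approx(expected, abs=1e-3)
        assert P.sum() == pytest.approx(1.0)

    def test_weighted_mean_matches_independent_computation(self):
        rng = np.random.default_rng(12)
        E = rng.uniform(-10, 2, size=(5, 8))
        amap = self._map_from_E(E)
        w = np.outer(np.sin(amap.grid.theta_values), np.ones(8))
        w /= w.sum()
        assert ua.average_simple(amap) == pytest.approx(float((w * E).sum()),
                                                        rel=1e-12)

    def test_boltzmann_below_simple_on_random_maps(self):
        """Canonical average never exceeds the arithmetic one (100 maps)."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            E = rng.normal(loc=rng.uniform(-8, 0), scale=rng.uniform(0.1, 5),
                           size=(7, 9))
            amap = self._map_from_E(E)
            e_b, P = ua.average_boltzmann(amap)
            assert e_b <= ua.average_simple(amap) + 1e-12
            assert np.all(P >= 0)
            assert P.sum() == pytest.approx(1.0)


class TestFacetAverage:
    def test_equal_weights(self):
        assert ua.facet_average({"100": -30.0, "110": -60.0, "111": -90.0}) == \
            pytest.approx(-60.0)

    def test_single_facet(self):
        assert ua.facet_average({"111": -42.0}) == -42.0

    def test_degenerate_weights(self):
        vals = {"100": -30.0, "110": -60.0, "111": -90.0}
        assert ua.facet_average(vals, {"100": 1.0, "110": 0.0, "111": 0.0}) == -30.0

    def test_missing_facet_with_weight(self):
        with pytest.raises(KeyError, match="110"):
            ua.facet_average({"100": -30.0}, {"100": 0.5, "110": 0.5})


class TestLowestEnergyPose:
    def test_single_bead_sole_contact(self, medium, slab_np, ala_table,
                                      single_ala):
        potset = make_potset(slab_np, medium, {"ALA": ala_table})
        amap = ua.orientation_map(single_ala, potset,
                                  ua.OrientationGrid.from_degrees(90))
        _, pdb_text, contacts = ua.lowest_energy_pose(amap, single_ala, potset)
        assert len(contacts) == 1
        assert contacts[0][0] == "ALA"
        assert "ATOM" in pdb_text

    def test_dumbbell_contact_is_engineered_binder(self, registry, medium,
                                                   slab_np):
        protein, _ = toy_protein(2, "dumbbell", bead_names=("ALA", "TRP"),
                                 spacing=1.0, registry=registry)
        potset = dumbbell_potset(slab_np, medium)
        amap = ua.orientation_map(protein, potset,
                                  ua.OrientationGrid.from_degrees(30))
        state, _, contacts = ua.lowest_energy_pose(amap, protein, potset)
        assert [c[0] for c in contacts] == ["TRP"]
        # the bound head sits near its PMF minimum at ~0.2 nm
        assert contacts[0][2] == pytest.approx(0.2, abs=0.05)

    def test_rerun_byte_identical(self, registry, medium, slab_np):
        protein, _ = toy_protein(2, "dumbbell", bead_names=("ALA", "TRP"),
                                 spacing=1.0, registry=registry)
        potset = dumbbell_potset(slab_np, medium)
        amap = ua.orientation_map(protein, potset,
                                  ua.OrientationGrid.from_degrees(45))
        out1 = ua.lowest_energy_pose(amap, protein, potset)
        out2 = ua.lowest_energy_pose(amap, protein, potset)
        assert out1[1] == out2[1]
        assert out1[2] == out2[2]


def test_zero_potential_limit_gives_exact_zero(registry, medium):
    """As PMFs, Hamaker constants and charges vanish, E_ads^A = E_ads^B = 0."""
    neutral = ua.NanoParticle(shape="slab", radius=None, surface_potential=0.0,
                              facet_weights={"111": 1.0})
    protein, _ = toy_protein(3, "line", registry=registry)
    potset = zero_potset(neutral, medium)
    amap = ua.orientation_map(protein, potset, ua.OrientationGrid.from_degrees(60))
    assert ua.average_simple(amap) == 0.0
    assert ua.average_boltzmann(amap)[0] == 0.0
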