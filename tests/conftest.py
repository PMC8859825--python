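import numpy as np
import pytest

import uamodel as ua
from uamodel.fixtures import SyntheticPMFSpec, synth_pmf, toy_protein


@pytest.fixture(scope="session")
def registry():
    return ua.BeadRegistry.default()


@pytest.fixture(scope="session")
def materials():
    return ua.load_materials()


@pytest.fixture(scope="session")
def medium():
    """0.15 M monovalent salt, eps 78.4, 300 K."""
    return ua.Medium()


@pytest.fixture(scope="session")
def slab_np():
    return ua.NanoParticle(
        shape="slab", radius=None, surface_potential=-25.0,
        facet_weights={"111": 1.0},
    )


@pytest.fixture(scope="session")
def sphere_np():
    return ua.NanoParticle(
        shape="sphere", radius=5.0, surface_potential=-25.0,
        facet_weights={"111": 1.0},
    )


def flat_zero_table(bead_name="ALA", facet="111", r_c=1.0):
    """A PMF table that is identically zero (non-interacting surface)."""
    grid = np.arange(0.08, r_c + 0.005, 0.01)
    return ua.SurfacePMFTable(
        bead_name=bead_name, facet=facet, grid=grid,
        values=np.zeros_like(grid), r_c=r_c, zero_ref=True,
    )


@pytest.fixture(scope="session")
def ala_table():
    return synth_pmf(SyntheticPMFSpec(bead_name="ALA", facet="111"))


@pytest.fixture(scope="session")
def single_ala(registry):
    protein, _ = toy_protein(1, "line", registry=registry)
    return protein


def make_potset(np_spec, medium, tables, hamaker=None, facet="111"):
    return ua.PotentialSet(
        np_spec=np_spec, medium=medium, tables=tables,
        hamaker=hamaker or {}, facet=facet,
    )
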