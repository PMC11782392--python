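import numpy as np
import pytest

from aaaprobe.constitutive import HGOWall, HGOWallParams, TissueParams
from aaaprobe.geometry import (GeometrySpec, make_geometry,
                               patient_archetypes, triangulate)


@pytest.fixture(scope="session")
def archetypes():
    return patient_archetypes()


@pytest.fixture(scope="session")
def p1_mesh(archetypes):
    """Triangulated default archetype, shared across the session."""
    return triangulate(make_geometry(archetypes["P1"]))


@pytest.fixture(scope="session")
def small_spec():
    """A deliberately coarse anatomy for fast solver tests."""
    return GeometrySpec(d_max=50.0, n_wall=40, mesh_size=4.0,
                        n_contour=128)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return triangulate(make_geometry(small_spec))


@pytest.fixture()
def hgo_params():
    return HGOWallParams()


@pytest.fixture()
def soft_tissue():
    return TissueParams(mu=5.0)
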