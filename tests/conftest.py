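import numpy as np
import pytest

from radcs.mesh_core import TriMesh
from radcs.synthetic_radius import RadiusShapeParams, generate_radius

from oracles import open_cylinder


@pytest.fixture
def tetra_mesh() -> TriMesh:
    verts = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    return TriMesh(verts, faces)


@pytest.fixture
def cylinder_mesh() -> TriMesh:
    v, f = open_cylinder(radius=10.0, height=100.0)
    return TriMesh(v, f)


@pytest.fixture(scope="session")
def small_radius():
    """One default synthetic radius with its ground truth (canonical frame)."""
    return generate_radius(RadiusShapeParams(seed=11))


@pytest.fixture(scope="session")
def straight_tube():
    """Symmetric limit: no bow, no flare, small styloid."""
    params = RadiusShapeParams(
        seed=4, bow_angle=0.0, flare_scale=1.0, styloid_height=5.0,
        shaft_radius_proximal=9.0, shaft_radius_distal=9.0,
    )
    return generate_radius(params)
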