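import numpy as np
import pytest

from fibmorph.mesh_core import CompartmentLabel, TriangleMesh
from fibmorph.synthetic_data import OrganelleSpec, Sphere, make_parametric_mesh


def cube_mesh(edge_nm: float = 1000.0, origin=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Closed unit cube with outward-oriented faces (12 triangles)."""
    o = np.asarray(origin, dtype=float)
    v = (
        np.array(
            [
                [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
            ],
            dtype=float,
        )
        * edge_nm
        + o
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (z=0), outward -z
            [4, 5, 6], [4, 6, 7],  # top
            [0, 1, 5], [0, 5, 4],  # front
            [1, 2, 6], [1, 6, 5],  # right
            [2, 3, 7], [2, 7, 6],  # back
            [3, 0, 4], [3, 4, 7],  # left
        ]
    )
    return TriangleMesh(v, f, CompartmentLabel("other"), "cube")


def icosphere(radius_nm: float = 1000.0, subdivision: int = 4, center=(0, 0, 0)):
    spec = OrganelleSpec("other", Sphere(tuple(float(c) for c in center), radius_nm))
    mesh, surf, vol = make_parametric_mesh(spec, subdivision=subdivision)
    return mesh, surf, vol


@pytest.fixture
def cube():
    return cube_mesh()


@pytest.fixture
def unit_sphere():
    mesh, surf, vol = icosphere(1000.0, 4)
    return mesh, surf, vol
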