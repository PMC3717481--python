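import numpy as np
import pytest

from plurigon import Plurigon, apply_radii, build_prototype_hull, place_points_spiral
from plurigon.meshing import octahedron
from plurigon.sphere import SpherePointSet
from plurigon.vector_io import DataVector


@pytest.fixture
def octa_plurigon() -> Plurigon:
    """Unit octahedron wrapped as a plurigon (6 vertices, all radii 1)."""
    mesh = octahedron()
    theta = np.arccos(np.clip(mesh.vertices[:, 2], -1, 1))
    phi = np.mod(np.arctan2(mesh.vertices[:, 1], mesh.vertices[:, 0]), 2 * np.pi)
    return Plurigon(
        mesh=mesh,
        points=SpherePointSet(theta, phi),
        source_values=np.ones(6),
    )


def make_plurigon(radii: np.ndarray) -> Plurigon:
    """Spiral prototype of len(radii) vertices deformed to the given radii."""
    radii = np.asarray(radii, dtype=float)
    pts = place_points_spiral(radii.size)
    proto = build_prototype_hull(pts)
    return apply_radii(proto, pts, DataVector(radii))


@pytest.fixture
def unit_sphere_200() -> Plurigon:
    return make_plurigon(np.ones(200))
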