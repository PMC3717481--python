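"""Prototype mesh construction: convex hull of the sphere points.

For points lying on a sphere, the Delaunay triangulation of the point set is
realized by its 3-D convex hull, and every point is extreme, so the hull
uses all n points as vertices. The hull is computed with Qhull (the
QuickHull algorithm) via scipy; the contract enforced here is our own:
vertex k of the mesh is input point k (the lossless vertex-to-dimension
map), all faces are triangles, the mesh is a closed 2-manifold with
V - E + F = 2, and all faces are oriented outward.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .errors import GeometryError
from .sphere import SpherePointSet

#: Faces with area below this (on a unit-scale mesh) count as degenerate.
DEGENERATE_AREA_TOL = 1e-12


@dataclass
class TriMesh:
    """A triangle mesh: (n, 3) float vertices and (m, 3) int faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise GeometryError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise GeometryError("faces must be an (m, 3) array")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def edges(self, directed: bool = False) -> np.ndarray:
        """All edges as index pairs; undirected edges are deduplicated."""
        e = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        if directed:
            return e
        return np.unique(np.sort(e, axis=1), axis=0)

    @property
    def n_edges(self) -> int:
        return int(self.edges().shape[0])

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_faces

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        nrm = np.cross(v1 - v0, v2 - v0)
        if normalize:
            lens = np.linalg.norm(nrm, axis=1, keepdims=True)
            lens[lens == 0] = 1.0
            nrm = nrm / lens
        return nrm

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.face_normals(normalize=False), axis=1)

    def signed_volume(self) -> float:
        """Volume by the divergence theorem w.r.t. the origin; positive when
        faces are consistently outward."""
        v0, v1, v2 = (self.vertices[self.faces[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())


@dataclass
class ValidationReport:
    """Topology/orientation report for a candidate closed triangulation."""

    is_manifold: bool
    euler_characteristic: int
    n_boundary_edges: int
    n_degenerate_faces: int
    orientation_consistent: bool
    signed_volume: float

    @property
    def passed(self) -> bool:
        return (
            self.is_manifold
            and self.euler_characteristic == 2
            and self.n_boundary_edges == 0
            and self.n_degenerate_faces == 0
            and self.orientation_consistent
            and self.signed_volume > 0
        )


def build_prototype_hull(pts: SpherePointSet) -> TriMesh:
    """Triangulate the point set by its convex hull, preserving point indices.

    Every input point must appear as a hull vertex; a point swallowed or
    merged by the hull would break the lossless vertex-to-dimension map and
    is a hard error.
    """
    xyz = pts.cartesian
    if xyz.shape[0] < 4:
        raise GeometryError("need at least 4 points for a 3-D hull")
    try:
        hull = ConvexHull(xyz)
    except Exception as exc:  # Qhull raises its own error class
        raise GeometryError(f"convex hull failed: {exc}") from exc
    used = np.unique(hull.simplices)
    if used.size != xyz.shape[0]:
        missing = sorted(set(range(xyz.shape[0])) - set(used.tolist()))
        raise GeometryError(
            f"{len(missing)} input points are not hull vertices "
            f"(first few: {missing[:5]}); vertex-to-dimension map would be lost"
        )
    mesh = TriMesh(xyz.copy(), hull.simplices.copy())
    return orient_outward(mesh)


def orient_outward(m: TriMesh) -> TriMesh:
    """Flip faces so every normal points away from the origin.

    Valid for meshes star-shaped about the origin (all plurigons are: each
    vertex sits on its own ray from the core). The mesh is modified on a
    copy and returned.
    """
    mesh = m.copy()
    normals = mesh.face_normals(normalize=False)
    centroids = mesh.face_centroids()
    inward = np.einsum("ij,ij->i", normals, centroids) < 0
    mesh.faces[inward] = mesh.faces[inward][:, [0, 2, 1]]
    if mesh.signed_volume() <= 0:
        raise GeometryError(
            "cannot orient mesh outward; is the origin inside the surface?"
        )
    return mesh


def validate_closed_triangulation(m: TriMesh) -> ValidationReport:
    """Check manifoldness, closure, Euler characteristic, degeneracy and
    orientation consistency. Always returns a report, never raises."""
    directed = m.edges(directed=True)
    und = np.sort(directed, axis=1)
    uniq, counts = np.unique(und, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    manifold = bool(np.all(counts == 2))
    # Orientation consistency: every undirected edge is traversed once in
    # each direction.
    dir_uniq, dir_counts = np.unique(directed, axis=0, return_counts=True)
    oriented = manifold and bool(np.all(dir_counts == 1))
    euler = m.n_vertices - uniq.shape[0] + m.n_faces
    scale = max(float(np.abs(m.vertices).max()), 1.0)
    degenerate = int((m.face_areas() < DEGENERATE_AREA_TOL * scale * scale).sum())
    return ValidationReport(
        is_manifold=manifold,
        euler_characteristic=int(euler),
        n_boundary_edges=boundary,
        n_degenerate_faces=degenerate,
        orientation_consistent=oriented,
        signed_volume=m.signed_volume(),
    )


def octahedron() -> TriMesh:
    """Unit octahedron (vertices on the coordinate axes), outward-oriented.

    Analytic reference solid used throughout the tests: V=6, E=12, F=8,
    surface area 4*sqrt(3), volume 4/3.
    """
    verts = np.array(
        [
            [1, 0, 0],
            [-1, 0, 0],
            [0, 1, 0],
            [0, -1, 0],
            [0, 0, 1],
            [0, 0, -1],
        ],
        dtype=float,
    )
    faces = np.array(
        [
            [0, 2, 4],
            [2, 1, 4],
            [1, 3, 4],
            [3, 0, 4],
            [2, 0, 5],
            [1, 2, 5],
            [3, 1, 5],
            [0, 3, 5],
        ]
    )
    return orient_outward(TriMesh(verts, faces))
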