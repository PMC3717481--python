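"""Radial deformation of the prototype and guarded Laplacian smoothing.

The prototype's unit radii are replaced by the (normalized, strictly
positive) data values: vertex k slides along its original direction
(theta_k, phi_k) to radius v[k]. The raw deformed surface is typically
turbulent; iterative Laplacian (umbrella) smoothing relaxes each vertex
toward the centroid of its edge neighbours until movement becomes
negligible. Topology is frozen at the prototype: smoothing never changes
the face array, and a guard rejects (by repeated halving) any vertex move
that would flip a face normal inward, so the mesh stays a valid
outward-oriented closed surface throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionalityError, GeometryError, PlurigonError
from .meshing import TriMesh
from .sphere import SpherePointSet
from .vector_io import DataVector

DEFAULT_LAMBDA = 0.5
DEFAULT_TOL = 1e-3
DEFAULT_MAX_ITER = 20

#: Maximum number of guard halvings before a vertex move is skipped entirely.
_GUARD_HALVINGS = 8

# Color anchors: low -> cyan, mid -> gray, high -> red.
_CYAN = np.array([0.0, 1.0, 1.0])
_GRAY = np.array([0.5, 0.5, 0.5])
_RED = np.array([1.0, 0.0, 0.0])


@dataclass
class Plurigon:
    """A deformed-sphere mesh carrying its source data.

    Attributes
    ----------
    mesh : TriMesh
        Current geometry; ``mesh.faces`` is identical to the prototype's at
        all times.
    points : SpherePointSet
        The prototype directions (theta_k, phi_k) per vertex.
    source_values : ndarray
        Original (pre-normalization) data value per vertex.
    colors : ndarray or None
        Per-vertex RGB in [0, 1]^3, set by :func:`colorize`.
    smoothing_log : list of float
        Max vertex displacement recorded at each smoothing iteration.
    vertex_to_dim : ndarray
        Permutation mapping vertex id -> original dimension (identity by
        construction; stable under smoothing).
    """

    mesh: TriMesh
    points: SpherePointSet
    source_values: np.ndarray
    colors: np.ndarray | None = None
    smoothing_log: list = field(default_factory=list)
    vertex_to_dim: np.ndarray = None

    def __post_init__(self):
        self.source_values = np.asarray(self.source_values, dtype=float)
        if self.vertex_to_dim is None:
            self.vertex_to_dim = np.arange(self.mesh.n_vertices)
        if self.mesh.n_vertices != self.source_values.size:
            raise DimensionalityError(
                f"{self.mesh.n_vertices} vertices but {self.source_values.size} values"
            )

    @property
    def n(self) -> int:
        return self.mesh.n_vertices

    @property
    def radii(self) -> np.ndarray:
        """Per-vertex distance to the origin (the core)."""
        return np.linalg.norm(self.mesh.vertices, axis=1)

    def copy(self) -> "Plurigon":
        return Plurigon(
            mesh=self.mesh.copy(),
            points=self.points,
            source_values=self.source_values.copy(),
            colors=None if self.colors is None else self.colors.copy(),
            smoothing_log=list(self.smoothing_log),
            vertex_to_dim=self.vertex_to_dim.copy(),
        )


def apply_radii(
    proto: TriMesh,
    pts: SpherePointSet,
    v: DataVector,
    source_values: np.ndarray | None = None,
) -> Plurigon:
    """Move vertex k of the prototype to radius v[k] along its direction.

    ``v`` must be normalized (all values strictly positive) and of length n.
    ``source_values`` optionally carries the pre-normalization data for
    coloring and reporting; defaults to ``v`` itself.
    """
    if len(v) != proto.n_vertices:
        raise DimensionalityError(
            f"vector length {len(v)} != prototype vertex count {proto.n_vertices}"
        )
    radii = v.values
    if np.any(radii <= 0):
        raise PlurigonError(
            "all radii must be strictly positive; normalize the vector first"
        )
    dirs = pts.cartesian
    mesh = TriMesh(radii[:, None] * dirs, proto.faces.copy())
    src = v.values if source_values is None else np.asarray(source_values, float)
    return Plurigon(mesh=mesh, points=pts, source_values=src)


def _vertex_adjacency(mesh: TriMesh):
    """Neighbour index list and a CSR-like flattened structure."""
    edges = mesh.edges()
    n = mesh.n_vertices
    neighbors: list[list[int]] = [[] for _ in range(n)]
    for a, b in edges:
        neighbors[a].append(b)
        neighbors[b].append(a)
    counts = np.array([len(nb) for nb in neighbors], dtype=float)
    flat = np.concatenate([np.array(nb, dtype=np.int64) for nb in neighbors])
    offsets = np.concatenate([[0], np.cumsum(counts).astype(np.int64)])
    return flat, offsets, counts


def _neighbor_centroids(vertices, flat, offsets, counts):
    sums = np.add.reduceat(vertices[flat], offsets[:-1], axis=0)
    return sums / counts[:, None]


def _inverted_faces(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Boolean mask of faces whose normal points inward (toward the core)."""
    v0, v1, v2 = (vertices[faces[:, i]] for i in range(3))
    normals = np.cross(v1 - v0, v2 - v0)
    centroids = (v0 + v1 + v2) / 3.0
    return np.einsum("ij,ij->i", normals, centroids) <= 0


def smooth_laplacian(
    p: Plurigon,
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    radial_only: bool = False,
) -> Plurigon:
    """Guarded iterative Laplacian (umbrella) smoothing.

    Per iteration, every vertex moves toward the centroid of its edge
    neighbours by factor ``lam``. Any move that would make an incident
    face's normal point inward is halved until valid, and skipped if still
    invalid after a few halvings. Iteration stops when the maximum
    displacement falls below ``tol`` times the mean radius, or after
    ``max_iter`` iterations. The face array is never touched.

    ``radial_only=True`` smooths the radii over the neighbour graph while
    keeping every vertex on its original ray, trading smoothness for strict
    per-dimension interpretability.
    """
    if not 0 < lam <= 1:
        raise ValueError(f"lambda must be in (0, 1], got {lam}")
    if max_iter < 0:
        raise ValueError("max_iter must be >= 0")
    out = p.copy()
    if max_iter == 0:
        return out
    mesh = out.mesh
    flat, offsets, counts = _vertex_adjacency(mesh)
    dirs = out.points.cartesian
    for _ in range(max_iter):
        verts = mesh.vertices
        if radial_only:
            radii = np.linalg.norm(verts, axis=1)
            nb_mean_r = np.add.reduceat(radii[flat], offsets[:-1]) / counts
            new_r = radii + lam * (nb_mean_r - radii)
            proposal = new_r[:, None] * dirs
        else:
            cent = _neighbor_centroids(verts, flat, offsets, counts)
            proposal = verts + lam * (cent - verts)
        displacement = proposal - verts
        # Guard: halve offending vertices' moves until no face inverts.
        candidate = verts + displacement
        for _halving in range(_GUARD_HALVINGS + 1):
            bad_faces = _inverted_faces(candidate, mesh.faces)
            if not bad_faces.any():
                break
            bad_vertices = np.unique(mesh.faces[bad_faces])
            if _halving == _GUARD_HALVINGS:
                displacement[bad_vertices] = 0.0
            else:
                displacement[bad_vertices] *= 0.5
            candidate = verts + displacement
        max_disp = float(np.linalg.norm(displacement, axis=1).max())
        mesh.vertices = candidate
        out.smoothing_log.append(max_disp)
        mean_radius = float(np.linalg.norm(candidate, axis=1).mean())
        if mean_radius > 0 and max_disp / mean_radius < tol:
            break
    out.mesh = mesh
    return out


def edge_roughness(p: Plurigon) -> float:
    """Sum over edges of the squared radius difference — the roughness metric
    that smoothing is expected to drive down monotonically at first."""
    r = p.radii
    edges = p.mesh.edges()
    d = r[edges[:, 0]] - r[edges[:, 1]]
    return float((d * d).sum())


def colorize(p: Plurigon) -> Plurigon:
    """Assign per-vertex colors from the source values.

    Values are min-max mapped to t in [0, 1]; t=0 is cyan (lowest scores),
    t=0.5 gray, t=1 red (highest scores), linearly interpolated per channel.
    Constant input colors every vertex gray. Returns a copy.
    """
    out = p.copy()
    vals = out.source_values
    lo, hi = float(vals.min()), float(vals.max())
    if hi > lo:
        t = (vals - lo) / (hi - lo)
    else:
        t = np.full_like(vals, 0.5)
    colors = np.empty((vals.size, 3))
    low = t <= 0.5
    u = np.where(low, t * 2.0, (t - 0.5) * 2.0)[:, None]
    colors[low] = _CYAN + u[low] * (_GRAY - _CYAN)
    colors[~low] = _GRAY + u[~low] * (_RED - _GRAY)
    out.colors = np.clip(colors, 0.0, 1.0)
    return out
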