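"""Global geometric features and convex/concave motif classification.

The built-in report mirrors the original tool's info box: center of mass
(the unweighted mean of vertex Cartesian coordinates), its magnitude
r = sqrt(x^2 + y^2 + z^2), the average radius to the core (mean vertex
distance to the origin), and the total surface area (Heron's formula summed
over faces).

Faces are classified convex ("v") or concave ("c") by a local protrusion
score: the face centroid's radius minus the mean centroid radius of its
three edge-adjacent faces. Ordered tuples of face calls form motif strings
such as "v-c-v"; an exhaustive search over face k-tuples finds the motif
that best separates two groups of plurigons sharing one prototype.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .deformation import Plurigon
from .errors import GeometryError, PlurigonError


@dataclass(frozen=True)
class FeatureSummary:
    """The info-box features, all on post-smoothing geometry by default."""

    com: tuple[float, float, float]
    r: float
    avg_rad_core: float
    surface_area: float

    def to_dict(self) -> dict:
        x, y, z = self.com
        return {
            "com": {"x": x, "y": y, "z": z},
            "r": self.r,
            "avg_rad_core": self.avg_rad_core,
            "surface_area": self.surface_area,
        }


@dataclass(frozen=True)
class ConvexityCall:
    """Per-face protrusion call: 'v' (convex) iff score > 0, else 'c'."""

    face_id: int
    call: str
    score: float


def compute_com(p: Plurigon) -> tuple[float, float, float]:
    """Unweighted arithmetic mean of the vertex Cartesian coordinates."""
    c = p.mesh.vertices.mean(axis=0)
    return (float(c[0]), float(c[1]), float(c[2]))


def com_magnitude(com) -> float:
    """Euclidean norm of the center of mass, r = (x^2 + y^2 + z^2)^(1/2)."""
    x, y, z = (float(v) for v in com)
    return math.sqrt(x * x + y * y + z * z)


def average_radius_core(p: Plurigon) -> float:
    """Mean vertex distance to the origin (the 'core')."""
    return float(p.radii.mean())


def triangle_area_heron(a: float, b: float, c: float) -> float:
    """Triangle area from side lengths via Heron's formula.

    Uses Kahan's numerically stable rearrangement
    sqrt((a+(b+c)) (c-(a-b)) (c+(a-b)) (a+(b-c)))/4 with sides sorted
    a >= b >= c, which keeps needle triangles accurate. Degenerate triangles
    (triangle inequality holding with equality) return 0; violations beyond
    a small tolerance raise.
    """
    a, b, c = sorted((float(a), float(b), float(c)), reverse=True)
    if c < 0:
        raise ValueError("side lengths must be non-negative")
    slack = c - (a - b)
    if slack < 0:
        if slack < -1e-9 * max(a, 1.0):
            raise ValueError(f"triangle inequality violated: sides ({a}, {b}, {c})")
        slack = 0.0
    return math.sqrt((a + (b + c)) * slack * (c + (a - b)) * (a + (b - c))) / 4.0


def surface_area(p: Plurigon) -> float:
    """Total surface area: Heron's formula applied to every face."""
    verts = p.mesh.vertices
    faces = p.mesh.faces
    e01 = np.linalg.norm(verts[faces[:, 0]] - verts[faces[:, 1]], axis=1)
    e12 = np.linalg.norm(verts[faces[:, 1]] - verts[faces[:, 2]], axis=1)
    e20 = np.linalg.norm(verts[faces[:, 2]] - verts[faces[:, 0]], axis=1)
    return float(
        sum(triangle_area_heron(a, b, c) for a, b, c in zip(e01, e12, e20))
    )


def compute_features(p: Plurigon) -> FeatureSummary:
    """Assemble the full feature summary from the current geometry."""
    com = compute_com(p)
    return FeatureSummary(
        com=com,
        r=com_magnitude(com),
        avg_rad_core=average_radius_core(p),
        surface_area=surface_area(p),
    )


def _face_adjacency(faces: np.ndarray) -> np.ndarray:
    """(m, 3) array: the three edge-adjacent faces of each face."""
    m = faces.shape[0]
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi in range(m):
        f = faces[fi]
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            edge_to_faces.setdefault(key, []).append(fi)
    adj: list[list[int]] = [[] for _ in range(m)]
    for fs in edge_to_faces.values():
        if len(fs) != 2:
            raise GeometryError("mesh is not a closed 2-manifold")
        a, b = fs
        adj[a].append(b)
        adj[b].append(a)
    return np.array(adj, dtype=np.int64)


def convexity_scores(p: Plurigon) -> np.ndarray:
    """Protrusion score per face: centroid radius minus the mean centroid
    radius of the three edge-adjacent faces. Positive = sticks out."""
    cent_r = np.linalg.norm(p.mesh.face_centroids(), axis=1)
    adj = _face_adjacency(p.mesh.faces)
    return cent_r - cent_r[adj].mean(axis=1)


def face_convexity(p: Plurigon, face_id: int) -> ConvexityCall:
    """Classify one face convex ('v', score > 0) or concave ('c', score <= 0).

    The tie rule (score exactly 0 -> 'c') keeps motif strings deterministic;
    on a perfect sphere all scores vanish and every face is called 'c'.
    """
    m = p.mesh.n_faces
    if not 0 <= face_id < m:
        raise IndexError(f"face id {face_id} out of range 0..{m - 1}")
    score = float(convexity_scores(p)[face_id])
    return ConvexityCall(face_id=face_id, call="v" if score > 0 else "c", score=score)


def motif_string(p: Plurigon, face_ids) -> str:
    """Hyphen-joined convexity calls for the given faces, e.g. 'v-c-v'."""
    face_ids = list(face_ids)
    if not face_ids:
        return ""
    m = p.mesh.n_faces
    for fid in face_ids:
        if not 0 <= fid < m:
            raise IndexError(f"face id {fid} out of range 0..{m - 1}")
    scores = convexity_scores(p)
    return "-".join("v" if scores[f] > 0 else "c" for f in face_ids)


@dataclass(frozen=True)
class MotifSearchResult:
    """Outcome of the exhaustive discriminative-motif search."""

    faces: tuple[int, ...]
    accuracy: float
    n_tuples_searched: int


def _call_matrix(group: list[Plurigon]) -> np.ndarray:
    return np.stack([convexity_scores(p) > 0 for p in group])


def select_discriminative_faces(
    group_a: list[Plurigon],
    group_b: list[Plurigon],
    k: int = 3,
    max_tuples: int = 500_000,
) -> MotifSearchResult:
    """Exhaustively search face k-tuples for the best group separator.

    For every k-tuple of faces, each sample yields a motif string; the
    separation accuracy is the best achievable two-class accuracy when each
    distinct string is assigned to its majority group. Returns the
    highest-accuracy tuple (ties broken toward the lexicographically
    smallest tuple). All plurigons must share one prototype.

    Raises if C(F, k) exceeds ``max_tuples`` — reduce dimensionality first.
    """
    if k < 1:
        raise ValueError("motif size k must be >= 1")
    if not group_a or not group_b:
        raise PlurigonError("both groups must be non-empty")
    shapes = {p.mesh.faces.shape for p in group_a + group_b}
    if len(shapes) != 1 or not all(
        np.array_equal(p.mesh.faces, group_a[0].mesh.faces)
        for p in group_a + group_b
    ):
        raise GeometryError("all plurigons must share one prototype triangulation")
    n_faces = group_a[0].mesh.n_faces
    n_tuples = math.comb(n_faces, k)
    if n_tuples > max_tuples:
        raise PlurigonError(
            f"C({n_faces}, {k}) = {n_tuples} exceeds the search budget "
            f"{max_tuples}; reduce dimensionality before the motif search"
        )
    calls_a = _call_matrix(group_a)  # (na, F) bool
    calls_b = _call_matrix(group_b)
    na, nb = calls_a.shape[0], calls_b.shape[0]
    total = na + nb
    weights = (1 << np.arange(k - 1, -1, -1)).astype(np.int64)
    n_patterns = 1 << k

    best_acc = -1.0
    best_tuple: tuple[int, ...] = ()
    combos_iter = itertools.combinations(range(n_faces), k)
    chunk_size = 8192
    searched = 0
    while True:
        chunk = list(itertools.islice(combos_iter, chunk_size))
        if not chunk:
            break
        combos = np.array(chunk, dtype=np.int64)  # (B, k)
        pat_a = calls_a[:, combos].astype(np.int64) @ weights  # (na, B)
        pat_b = calls_b[:, combos].astype(np.int64) @ weights
        correct = np.zeros(combos.shape[0], dtype=np.int64)
        for pattern in range(n_patterns):
            ca = (pat_a == pattern).sum(axis=0)
            cb = (pat_b == pattern).sum(axis=0)
            correct += np.maximum(ca, cb)
        accs = correct / total
        i = int(np.argmax(accs))
        # Lexicographic tie-break falls out of iteration order: only a
        # strictly better tuple replaces the incumbent.
        if accs[i] > best_acc:
            best_acc = float(accs[i])
            best_tuple = tuple(int(x) for x in combos[i])
        searched += combos.shape[0]
    return MotifSearchResult(
        faces=best_tuple, accuracy=best_acc, n_tuples_searched=searched
    )


def vertex_to_dimension(p: Plurigon, vertex_id: int) -> int:
    """Map a mesh vertex back to its original data dimension.

    The map is the identity by construction and is unaffected by smoothing,
    which is what makes the representation lossless.
    """
    if not 0 <= vertex_id < p.n:
        raise IndexError(f"vertex id {vertex_id} out of range 0..{p.n - 1}")
    return int(p.vertex_to_dim[vertex_id])
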