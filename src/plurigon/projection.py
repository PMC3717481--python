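"""Silhouette outlines and scan-line length profiles.

Small rotations of a plurigon can hide or reveal surface features
("crypticism"). To quantify this, the mesh is orthographically projected
for a given view, its silhouette (the edges separating front-facing from
back-facing triangles) is chained into a closed outline loop, and the
outline is probed with m equally spaced parallel scan lines from one side
of its bounding box; each scan line's length is the distance from the box
edge to its first intersection with the outline. Profiles taken at two
views (or from two plurigons) are compared with a small integer index
shift, reporting the shift that minimizes the mean absolute difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import LineString

from .deformation import Plurigon
from .errors import GeometryError

DIRECTIONS = ("left", "right", "top", "bottom")
DEFAULT_SCAN_LINES = 64


@dataclass(frozen=True)
class OutlineTrace:
    """Closed silhouette polyline in projection-plane coordinates.

    ``loop`` is an (L, 2) array with ``loop[0] == loop[-1]``; ``view`` is
    the (azimuth, elevation) pair in degrees that produced it.
    """

    view: tuple[float, float]
    loop: np.ndarray
    bbox: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax

    @property
    def extent(self) -> tuple[float, float]:
        xmin, xmax, ymin, ymax = self.bbox
        return (xmax - xmin, ymax - ymin)


@dataclass(frozen=True)
class ScanProfile:
    """Lengths of m parallel scan lines fired from one side of the box."""

    direction: str
    lengths: np.ndarray
    spacing: float
    extent: float  # full box extent along the scan direction


def view_basis(azimuth: float, elevation: float):
    """Right/up/forward unit vectors of an orthographic camera.

    The camera looks toward the origin from the direction given by the
    azimuth (degrees, about +z from +x) and elevation (degrees above the
    xy-plane). ``forward`` points from the scene to the eye, so larger
    depth = closer.
    """
    az = np.radians(azimuth)
    el = np.radians(elevation)
    forward = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    if not np.all(np.isfinite(forward)) or np.linalg.norm(forward) < 1e-12:
        raise GeometryError("degenerate view direction")
    world_up = np.array([0.0, 0.0, 1.0])
    right = np.cross(world_up, forward)
    if np.linalg.norm(right) < 1e-9:  # looking straight down an axis pole
        right = np.cross(np.array([0.0, 1.0, 0.0]), forward)
    right /= np.linalg.norm(right)
    up = np.cross(forward, right)
    return right, up, forward


def _chain_loops(edges: list[tuple[int, int]]) -> list[list[int]]:
    """Chain undirected edges into closed vertex loops."""
    adjacency: dict[int, list[int]] = {}
    for a, b in edges:
        adjacency.setdefault(a, []).append(b)
        adjacency.setdefault(b, []).append(a)
    unused = {tuple(sorted(e)) for e in edges}
    loops = []
    while unused:
        start_edge = min(unused)
        unused.discard(start_edge)
        a, b = start_edge
        loop = [a, b]
        current, prev = b, a
        while True:
            nxt = None
            for cand in adjacency[current]:
                key = tuple(sorted((current, cand)))
                if cand != prev and key in unused:
                    nxt = cand
                    break
            if nxt is None:
                break
            unused.discard(tuple(sorted((current, nxt))))
            loop.append(nxt)
            prev, current = current, nxt
            if current == loop[0]:
                break
        if loop[0] == loop[-1] and len(loop) > 3:
            loops.append(loop[:-1])
    return loops


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def silhouette_outline(
    p: Plurigon, azimuth: float = 0.0, elevation: float = 0.0
) -> OutlineTrace:
    """Extract the outer silhouette loop under an orthographic view.

    Silhouette edges are mesh edges whose two incident faces face opposite
    half-spaces with respect to the view direction. They are chained into
    loops; the loop with the largest projected area (the outer outline) is
    returned closed (first point repeated at the end). Occluded/inner loops
    are discarded.
    """
    right, up, forward = view_basis(azimuth, elevation)
    normals = p.mesh.face_normals()
    front = normals @ forward > 0
    # Map each undirected edge to its two incident faces.
    faces = p.mesh.faces
    edge_faces: dict[tuple[int, int], list[int]] = {}
    for fi, f in enumerate(faces):
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            key = (int(a), int(b)) if a < b else (int(b), int(a))
            edge_faces.setdefault(key, []).append(fi)
    sil_edges = []
    for (a, b), fs in edge_faces.items():
        if len(fs) != 2:
            raise GeometryError("silhouette extraction needs a closed mesh")
        if front[fs[0]] != front[fs[1]]:
            sil_edges.append((a, b))
    if not sil_edges:
        raise GeometryError("no silhouette edges found for this view")
    proj = np.column_stack((p.mesh.vertices @ right, p.mesh.vertices @ up))
    loops = _chain_loops(sil_edges)
    if not loops:
        raise GeometryError("silhouette edges did not close into a loop")
    best = max(loops, key=lambda lp: _polygon_area(proj[np.array(lp)]))
    pts = proj[np.array(best)]
    closed = np.vstack([pts, pts[:1]])
    xmin, ymin = closed.min(axis=0)
    xmax, ymax = closed.max(axis=0)
    return OutlineTrace(
        view=(float(azimuth), float(elevation)),
        loop=closed,
        bbox=(float(xmin), float(xmax), float(ymin), float(ymax)),
    )


def scan_profile(
    t: OutlineTrace, direction: str = "left", m: int = DEFAULT_SCAN_LINES
) -> ScanProfile:
    """Fire m equally spaced scan lines from one side of the bounding box.

    Each length is the distance from the box edge to the first intersection
    with the outline; lines that miss the outline get the full box extent,
    keeping the profile numeric and comparable. The profile is invariant to
    uniform translation of the trace.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if m < 2:
        raise ValueError("need at least 2 scan lines")
    xmin, xmax, ymin, ymax = t.bbox
    outline = LineString(t.loop)
    horizontal = direction in ("left", "right")
    if horizontal:
        positions = np.linspace(ymin, ymax, m)
        extent = xmax - xmin
        spacing = (ymax - ymin) / (m - 1)
    else:
        positions = np.linspace(xmin, xmax, m)
        extent = ymax - ymin
        spacing = (xmax - xmin) / (m - 1)
    lengths = np.empty(m)
    for i, pos in enumerate(positions):
        if horizontal:
            seg = LineString([(xmin, pos), (xmax, pos)])
        else:
            seg = LineString([(pos, ymin), (pos, ymax)])
        inter = seg.intersection(outline)
        if inter.is_empty:
            lengths[i] = extent
            continue
        coords = []
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            coords.extend(np.asarray(g.coords))
        coords = np.asarray(coords)
        if direction == "left":
            lengths[i] = coords[:, 0].min() - xmin
        elif direction == "right":
            lengths[i] = xmax - coords[:, 0].max()
        elif direction == "bottom":
            lengths[i] = coords[:, 1].min() - ymin
        else:  # top
            lengths[i] = ymax - coords[:, 1].max()
    return ScanProfile(
        direction=direction,
        lengths=lengths,
        spacing=float(spacing),
        extent=float(extent),
    )


def compare_profiles(a: ScanProfile, b: ScanProfile, max_shift: int = 3) -> dict:
    """Match two profiles under small integer index shifts.

    For each shift s in [-max_shift, max_shift], profile b is realigned so
    index i of a is compared with index i + s of b over the overlapping
    range, and the mean absolute difference is computed. Returns the
    minimizing shift with its MAE and max-absolute difference; ties prefer
    the smaller |shift|, then the smaller shift.
    """
    if a.direction != b.direction:
        raise ValueError("profiles must share a scan direction")
    if a.lengths.size != b.lengths.size:
        raise ValueError("profiles must have the same number of scan lines")
    m = a.lengths.size
    if max_shift < 0 or max_shift >= m:
        raise ValueError("max_shift must be in [0, m)")
    best = None
    for s in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        if s >= 0:
            diff = a.lengths[: m - s] - b.lengths[s:]
        else:
            diff = a.lengths[-s:] - b.lengths[: m + s]
        mae = float(np.abs(diff).mean())
        max_abs = float(np.abs(diff).max())
        if best is None or mae < best["mae"]:
            best = {"mae": mae, "max_abs": max_abs, "best_shift": s}
    return best


def write_profile_tsv(profile: ScanProfile, path) -> None:
    """Two-column TSV: scan-line index, length."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, length in enumerate(profile.lengths):
            fh.write(f"{i}\t{float(length)!r}\n")


def write_trace_tsv(trace: OutlineTrace, path) -> None:
    """Two-column TSV of the closed loop coordinates."""
    with open(path, "w", encoding="utf-8") as fh:
        for x, y in trace.loop:
            fh.write(f"{float(x)!r}\t{float(y)!r}\n")
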