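"""Mesh serialization (VRML 2.0 / OBJ / ascii PLY), static rendering and
the JSON feature report.

All three mesh formats carry vertices, triangular faces and per-vertex
colors, and round-trip: ``import_mesh(export_mesh(p))`` reproduces the
vertex coordinates (to float formatting precision, 17 significant digits,
i.e. exactly for doubles) and the face indices. PLY stores colors as the
conventional 8-bit red/green/blue properties, so colors round-trip to
1/255.

Rendering is a deterministic orthographic painter's-algorithm rasterizer
on Pillow: faces are depth-sorted and filled back to front with their mean
vertex color, modulated by a fixed view-dependent shade. Optional overlays
follow the original tool's conventions: pink/yellow/blue x/y/z axes and a
red center-of-mass vector from the origin. Anaglyph stereo combines the
red channel of a left view with the green/blue channels of a right view
rotated by the eye-separation angle.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw

from .deformation import Plurigon
from .errors import ParseError, PlurigonError
from .features import FeatureSummary, compute_com
from .meshing import TriMesh, validate_closed_triangulation
from .projection import view_basis

_FMT = ".17g"

AXIS_COLORS = {  # pink, yellow, blue for x, y, z
    "x": (255, 105, 180),
    "y": (255, 215, 0),
    "z": (65, 105, 225),
}
COM_COLOR = (255, 0, 0)


@dataclass(frozen=True)
class RenderSpec:
    """Static-render configuration (the CLI flags behind the old hotkeys)."""

    azimuth: float = 30.0
    elevation: float = 20.0
    zoom: float = 1.0
    axes: bool = False
    com_vector: bool = False
    anaglyph: bool = False
    eye_separation: float = 5.0  # degrees between the two anaglyph views
    size: tuple[int, int] = (512, 512)
    background: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self):
        if self.zoom <= 0:
            raise ValueError("zoom must be positive")
        if min(self.size) < 64:
            raise ValueError("image dimensions must be at least 64 px")


# ---------------------------------------------------------------------------
# mesh serialization


def _f(x: float) -> str:
    return format(float(x), _FMT)


def _colors_or_gray(p) -> np.ndarray:
    if getattr(p, "colors", None) is not None:
        return np.asarray(p.colors, dtype=float)
    n = p.mesh.n_vertices if isinstance(p, Plurigon) else p.n_vertices
    return np.full((n, 3), 0.5)


def _infer_format(path, fmt: str | None) -> str:
    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = {"vrml": "wrl"}.get(fmt, fmt)
    if fmt not in ("wrl", "obj", "ply"):
        raise PlurigonError(f"unknown mesh format {fmt!r}; expected wrl, obj or ply")
    return fmt


def export_mesh(p: Plurigon | TriMesh, path, fmt: str | None = None) -> None:
    """Write the mesh with per-vertex colors in the requested format."""
    fmt = _infer_format(path, fmt)
    mesh = p.mesh if isinstance(p, Plurigon) else p
    colors = _colors_or_gray(p)
    verts, faces = mesh.vertices, mesh.faces
    lines: list[str] = []
    if fmt == "obj":
        for v, c in zip(verts, colors):
            lines.append(
                "v " + " ".join(_f(x) for x in v) + " " + " ".join(_f(x) for x in c)
            )
        for f in faces:
            lines.append("f " + " ".join(str(int(i) + 1) for i in f))
    elif fmt == "ply":
        rgb = np.clip(np.rint(colors * 255), 0, 255).astype(int)
        lines += [
            "ply",
            "format ascii 1.0",
            f"element vertex {mesh.n_vertices}",
            "property float x",
            "property float y",
            "property float z",
            "property uchar red",
            "property uchar green",
            "property uchar blue",
            f"element face {mesh.n_faces}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        for v, c in zip(verts, rgb):
            lines.append(" ".join(_f(x) for x in v) + f" {c[0]} {c[1]} {c[2]}")
        for f in faces:
            lines.append("3 " + " ".join(str(int(i)) for i in f))
    else:  # wrl — VRML 2.0 IndexedFaceSet with per-vertex colors
        pts = ",\n".join("      " + " ".join(_f(x) for x in v) for v in verts)
        cols = ",\n".join("      " + " ".join(_f(x) for x in c) for c in colors)
        idx = ",\n".join(
            "      " + ", ".join(str(int(i)) for i in f) + ", -1" for f in faces
        )
        lines = [
            "#VRML V2.0 utf8",
            "Shape {",
            "  geometry IndexedFaceSet {",
            "    solid TRUE",
            "    colorPerVertex TRUE",
            "    coord Coordinate { point [",
            pts,
            "    ] }",
            "    color Color { color [",
            cols,
            "    ] }",
            "    coordIndex [",
            idx,
            "    ]",
            "  }",
            "}",
        ]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


@dataclass
class ImportedMesh:
    """Geometry (and colors) read back from a mesh file; no source values."""

    mesh: TriMesh
    colors: np.ndarray | None = None


def import_mesh(path, fmt: str | None = None) -> ImportedMesh:
    """Parse a mesh written by :func:`export_mesh`; validates the result."""
    fmt = _infer_format(path, fmt)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if fmt == "obj":
        out = _parse_obj(text)
    elif fmt == "ply":
        out = _parse_ply(text)
    else:
        out = _parse_wrl(text)
    report = validate_closed_triangulation(out.mesh)
    if not report.is_manifold or report.n_boundary_edges:
        raise ParseError(f"{path}: imported mesh is not a closed manifold")
    return out


def _parse_obj(text: str) -> ImportedMesh:
    verts, colors, faces = [], [], []
    for lineno, line in enumerate(text.splitlines(), 1):
        tok = line.split()
        if not tok or tok[0].startswith("#"):
            continue
        try:
            if tok[0] == "v":
                vals = [float(x) for x in tok[1:]]
                if len(vals) not in (3, 6):
                    raise ValueError
                verts.append(vals[:3])
                if len(vals) == 6:
                    colors.append(vals[3:])
            elif tok[0] == "f":
                idx = [int(t.split("/")[0]) - 1 for t in tok[1:]]
                if len(idx) != 3:
                    raise ValueError
                faces.append(idx)
        except ValueError:
            raise ParseError(f"malformed OBJ record: {line!r}", line=lineno) from None
    if not verts or not faces:
        raise ParseError("OBJ file holds no complete mesh")
    mesh = TriMesh(np.array(verts), np.array(faces))
    cols = np.array(colors) if len(colors) == len(verts) else None
    return ImportedMesh(mesh=mesh, colors=cols)


def _parse_ply(text: str) -> ImportedMesh:
    lines = text.splitlines()
    if not lines or lines[0].strip() != "ply":
        raise ParseError("not a PLY file", line=1)
    n_vert = n_face = None
    body_start = None
    for i, line in enumerate(lines[1:], 2):
        tok = line.split()
        if tok[:2] == ["element", "vertex"]:
            n_vert = int(tok[2])
        elif tok[:2] == ["element", "face"]:
            n_face = int(tok[2])
        elif tok[:1] == ["end_header"]:
            body_start = i
            break
    if body_start is None or n_vert is None or n_face is None:
        raise ParseError("PLY header incomplete")
    body = lines[body_start:]
    if len(body) < n_vert + n_face:
        raise ParseError(
            f"PLY body truncated: expected {n_vert + n_face} records, "
            f"got {len(body)}"
        )
    verts, colors, faces = [], [], []
    try:
        for line in body[:n_vert]:
            vals = line.split()
            verts.append([float(x) for x in vals[:3]])
            colors.append([int(x) / 255.0 for x in vals[3:6]])
        for line in body[n_vert : n_vert + n_face]:
            vals = [int(x) for x in line.split()]
            if vals[0] != 3:
                raise ParseError("only triangular PLY faces are supported")
            faces.append(vals[1:4])
    except (ValueError, IndexError):
        raise ParseError("malformed PLY body record") from None
    return ImportedMesh(
        mesh=TriMesh(np.array(verts), np.array(faces)), colors=np.array(colors)
    )


def _extract_bracket(text: str, anchor: str) -> str:
    start = text.index(anchor) + len(anchor)
    start = text.index("[", start) + 1
    end = text.index("]", start)
    return text[start:end]


def _parse_wrl(text: str) -> ImportedMesh:
    if not text.startswith("#VRML V2.0"):
        raise ParseError("missing '#VRML V2.0 utf8' header", line=1)
    try:
        pts = _extract_bracket(text, "point")
        cols = _extract_bracket(text, "color Color { color")
        idx = _extract_bracket(text, "coordIndex")
    except ValueError:
        raise ParseError("VRML IndexedFaceSet fields not found") from None
    verts = np.array(
        [float(x) for x in pts.replace(",", " ").split()]
    ).reshape(-1, 3)
    colors = np.array(
        [float(x) for x in cols.replace(",", " ").split()]
    ).reshape(-1, 3)
    raw_idx = [int(x) for x in idx.replace(",", " ").split()]
    faces, cur = [], []
    for v in raw_idx:
        if v == -1:
            if len(cur) != 3:
                raise ParseError("non-triangular VRML face")
            faces.append(cur)
            cur = []
        else:
            cur.append(v)
    if cur:
        raise ParseError("VRML coordIndex not terminated with -1")
    return ImportedMesh(
        mesh=TriMesh(verts, np.array(faces)), colors=colors
    )


# ---------------------------------------------------------------------------
# rendering


def _project(vertices: np.ndarray, azimuth: float, elevation: float):
    right, up, forward = view_basis(azimuth, elevation)
    xy = np.column_stack((vertices @ right, vertices @ up))
    depth = vertices @ forward
    return xy, depth, forward


def _render_array(p: Plurigon, spec: RenderSpec, azimuth: float) -> np.ndarray:
    """Rasterize one orthographic view to an (H, W, 3) uint8 array."""
    mesh = p.mesh
    colors = _colors_or_gray(p)
    xy, depth, forward = _project(mesh.vertices, azimuth, spec.elevation)
    w, h = spec.size
    max_r = float(np.linalg.norm(mesh.vertices, axis=1).max())
    scale = spec.zoom * 0.4 * min(w, h) / max(max_r, 1e-12)

    def to_px(points2d: np.ndarray) -> np.ndarray:
        px = np.empty_like(points2d)
        px[:, 0] = w / 2.0 + points2d[:, 0] * scale
        px[:, 1] = h / 2.0 - points2d[:, 1] * scale
        return px

    px = to_px(xy)
    img = Image.new("RGB", (w, h), spec.background)
    draw = ImageDraw.Draw(img)
    # Painter's algorithm: draw back-to-front by mean face depth.
    face_depth = depth[mesh.faces].mean(axis=1)
    order = np.argsort(face_depth, kind="stable")
    normals = mesh.face_normals()
    shade = 0.55 + 0.45 * np.abs(normals @ forward)
    face_rgb = colors[mesh.faces].mean(axis=1) * shade[:, None]
    face_rgb = np.clip(np.rint(face_rgb * 255), 0, 255).astype(int)
    for fi in order:
        tri = [tuple(pt) for pt in px[mesh.faces[fi]]]
        draw.polygon(tri, fill=tuple(face_rgb[fi]))
    if spec.axes:
        L = 1.3 * max_r
        for axis, vec in zip("xyz", np.eye(3)):
            seg = np.array([[0.0, 0.0, 0.0], L * vec])
            seg_xy, _, _ = _project(seg, azimuth, spec.elevation)
            a, b = to_px(seg_xy)
            draw.line([tuple(a), tuple(b)], fill=AXIS_COLORS[axis], width=2)
    if spec.com_vector:
        com = np.array(compute_com(p))
        seg = np.array([[0.0, 0.0, 0.0], com])
        seg_xy, _, _ = _project(seg, azimuth, spec.elevation)
        a, b = to_px(seg_xy)
        draw.line([tuple(a), tuple(b)], fill=COM_COLOR, width=3)
    return np.asarray(img)


def _save_array(arr: np.ndarray, path) -> None:
    Image.fromarray(arr).save(path)


def render_view(p: Plurigon, spec: RenderSpec, path) -> None:
    """Deterministic orthographic snapshot (PNG or TIFF by extension)."""
    _save_array(_render_array(p, spec, spec.azimuth), path)


def render_anaglyph(p: Plurigon, spec: RenderSpec, path) -> None:
    """Red/cyan stereo: red channel from the left view, green+blue from the
    right view, the two views separated by ``spec.eye_separation`` degrees."""
    delta = spec.eye_separation / 2.0
    left = _render_array(p, spec, spec.azimuth - delta)
    right = _render_array(p, spec, spec.azimuth + delta)

    def gray(a: np.ndarray) -> np.ndarray:
        return (a @ np.array([0.299, 0.587, 0.114])).astype(np.uint8)

    gl, gr = gray(left), gray(right)
    out = np.stack([gl, gr, gr], axis=-1)
    _save_array(out, path)


# ---------------------------------------------------------------------------
# feature report

_REPORT_KEYS = ("com", "r", "avg_rad_core", "surface_area")


def write_feature_report(f: FeatureSummary, path) -> None:
    """JSON mirror of the info box, at full double precision."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(f.to_dict(), fh, indent=2)
        fh.write("\n")


def read_feature_report(path) -> FeatureSummary:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    missing = [k for k in _REPORT_KEYS if k not in data]
    if missing:
        raise ParseError(f"feature report missing fields: {missing}")
    com = data["com"]
    if not all(k in com for k in "xyz"):
        raise ParseError("feature report com must carry x, y and z")
    return FeatureSummary(
        com=(com["x"], com["y"], com["z"]),
        r=data["r"],
        avg_rad_core=data["avg_rad_core"],
        surface_area=data["surface_area"],
    )
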