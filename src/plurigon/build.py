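"""End-to-end construction: data vector -> smoothed, colorized plurigon."""

from __future__ import annotations

import numpy as np

from .deformation import (
    DEFAULT_LAMBDA,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    Plurigon,
    apply_radii,
    colorize,
    smooth_laplacian,
)
from .meshing import build_prototype_hull
from .sphere import place_points_spiral
from .vector_io import DEFAULT_TARGET, DataVector, normalize_values


def build_plurigon(
    v: DataVector,
    normalize: bool = True,
    target: tuple[float, float] = DEFAULT_TARGET,
    lam: float = DEFAULT_LAMBDA,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    radial_only: bool = False,
    endpoint_offset: float = 0.5,
) -> Plurigon:
    """Run the full pipeline on one vector.

    Spiral placement of n = len(v) points, convex-hull triangulation, radius
    replacement with the min-max-normalized values, guarded Laplacian
    smoothing, and color coding from the original (pre-normalization)
    values. Set ``max_iter=0`` for the raw deformed surface.
    """
    v.require_dimensionality()
    pts = place_points_spiral(len(v), endpoint_offset=endpoint_offset)
    proto = build_prototype_hull(pts)
    radii = normalize_values(v, target) if normalize else v
    if not normalize and np.any(v.values <= 0):
        raise ValueError(
            "raw values must be strictly positive when normalize=False"
        )
    p = apply_radii(proto, pts, radii, source_values=v.values)
    p = smooth_laplacian(p, lam=lam, tol=tol, max_iter=max_iter,
                         radial_only=radial_only)
    return colorize(p)
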