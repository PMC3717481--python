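"""Quasi-equidistant point placement on the unit sphere by spiral tracing.

Equally spacing n points on a sphere is only exact for the platonic counts;
for arbitrary n the generalized spiral construction places points at equal
arc steps along a pole-to-pole spiral, which runs in linear time and keeps
the variance of nearest-neighbour distances small. A naive equal-angle
(theta, phi) lattice concentrates points near the poles; the spiral does not.

The recurrence used here (with point index k = 1..n):

    h_k   = -1 + 2 (k - 1 + eps) / (n - 1 + 2 eps)
    theta_k = arccos(h_k)
    phi_1 = 0
    phi_k = (phi_{k-1} + C / sqrt(n (1 - h_k^2))) mod 2 pi,  C = 3.6

The endpoint offset eps > 0 pulls the first and last points off the exact
poles, enlarging the gap between the highest and lowest points, which
improves sparseness at the poles. eps is exposed because no canonical value
exists; 0.5 is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DimensionalityError

SPIRAL_C = 3.6
DEFAULT_ENDPOINT_OFFSET = 0.5


@dataclass(frozen=True)
class SpherePointSet:
    """n ordered points on the unit sphere in spherical coordinates.

    Index k is the permanent identity linking point k to data dimension k.
    ``theta`` is the colatitude from +z in [0, pi]; ``phi`` the longitude
    in [0, 2 pi).
    """

    theta: np.ndarray
    phi: np.ndarray

    def __post_init__(self):
        th = np.asarray(self.theta, dtype=float)
        ph = np.asarray(self.phi, dtype=float)
        if th.shape != ph.shape or th.ndim != 1:
            raise ValueError("theta and phi must be equal-length 1-D arrays")
        object.__setattr__(self, "theta", th)
        object.__setattr__(self, "phi", ph)

    @property
    def n(self) -> int:
        return int(self.theta.size)

    def __len__(self) -> int:
        return self.n

    @property
    def cartesian(self) -> np.ndarray:
        """(n, 3) unit Cartesian coordinates; right-handed, colatitude from +z."""
        st = np.sin(self.theta)
        return np.column_stack(
            (st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta))
        )


def place_points_spiral(
    n: int,
    endpoint_offset: float = DEFAULT_ENDPOINT_OFFSET,
    c: float = SPIRAL_C,
) -> SpherePointSet:
    """Trace n points pole-to-pole along a generalized spherical spiral.

    Deterministic, O(n). Points are returned south-to-north in trace order.

    Raises
    ------
    DimensionalityError
        If n < 4 (no closed triangulated surface exists below that).
    """
    if n < 4:
        raise DimensionalityError(f"need n >= 4 points, got {n}")
    k = np.arange(1, n + 1, dtype=float)
    eps = float(endpoint_offset)
    h = -1.0 + 2.0 * (k - 1.0 + eps) / (n - 1.0 + 2.0 * eps)
    theta = np.arccos(np.clip(h, -1.0, 1.0))
    # phi recurrence: cumulative sum of the per-step longitude increments.
    step = c / np.sqrt(n * (1.0 - h * h))
    step[0] = 0.0
    phi = np.mod(np.cumsum(step), 2.0 * np.pi)
    return SpherePointSet(theta=theta, phi=phi)


def place_points_naive_grid(n: int) -> SpherePointSet:
    """Equal-angle (theta, phi) lattice with ~n points — the poor baseline.

    Rows are equally spaced in colatitude and columns in longitude, so the
    areal density blows up near the poles. Provided for comparison against
    the spiral; never used in the pipeline.
    """
    if n < 4:
        raise DimensionalityError(f"need n >= 4 points, got {n}")
    rows = max(2, int(round(np.sqrt(n))))
    cols = max(2, int(np.ceil(n / rows)))
    theta = []
    phi = []
    made = 0
    for i in range(rows):
        t = np.pi * (i + 0.5) / rows
        for j in range(cols):
            if made == n:
                break
            theta.append(t)
            phi.append(2.0 * np.pi * j / cols)
            made += 1
    return SpherePointSet(theta=np.array(theta), phi=np.array(phi))


def spacing_statistics(pts: SpherePointSet) -> dict:
    """Exact brute-force nearest-neighbour chord-distance statistics.

    Chord (3-D Euclidean) distance is the spacing metric: it is monotone in
    the great-circle distance on the sphere and is what hull geometry sees.
    O(n^2); this function is itself the oracle, so no approximation is used.

    Returns ``{"min", "mean", "max", "cv"}`` of the per-point
    nearest-neighbour distance (cv = std / mean).
    """
    xyz = pts.cartesian
    if len(pts) < 2:
        raise DimensionalityError("need at least 2 points for spacing statistics")
    D = squareform(pdist(xyz))
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    mean = float(nn.mean())
    return {
        "min": float(nn.min()),
        "mean": mean,
        "max": float(nn.max()),
        "cv": float(nn.std() / mean) if mean > 0 else float("inf"),
    }
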