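# Methods

This note documents the models, numerical choices and limitations behind
the package; the README covers usage.

## Representation

A data vector **v** ∈ ℝⁿ is encoded as a closed triangle mesh whose vertex
k sits at spherical coordinates (r = v_k after normalization, θ_k, φ_k),
where (θ_k, φ_k) is the k-th point of a deterministic spiral trace of the
unit sphere. The encoding is lossless in the sense that the map
vertex ↔ dimension is the identity permutation and is never disturbed:
radii carry the magnitudes, angular positions carry the ordering. All
geometry lives in a right-handed frame with the origin at the sphere
center (the "core") and colatitude measured from +z.

## Spiral placement

Points are placed by the generalized spiral recurrence (README, step 1).
Properties relied on downstream:

* O(n) and fully deterministic — equal n gives bitwise-equal coordinates.
* Nearest-neighbour chord distances are tightly clustered (CV ≈ 0.02 at
  n = 1000, vs ≈ 0.31 for an equal-angle lattice at the same n); the polar
  caps hold no more than twice their equal-area share of points.
* Chord (3-D Euclidean) distance is the spacing metric throughout: it is
  monotone in the great-circle distance on a sphere and is what the hull
  sees. `spacing_statistics` computes the exact O(n²) statistics and is
  itself the oracle used in tests.

The endpoint offset ε has no canonical published value; it is exposed
(default 0.5, i.e. first/last points half a step off the poles). The
spiral constant C = 3.6 follows the standard construction.

## Triangulation

For points on a sphere, the Delaunay triangulation is realized by the 3-D
convex hull, and every point is extreme. The hull is computed with Qhull
(QuickHull) through scipy; our wrapper enforces the contract Qhull does
not know about: every input point must appear among the hull vertices
(a merged or swallowed point would silently break the vertex↔dimension
map and is a hard error), faces are triangles, and faces are re-wound to
point outward (valid because every plurigon is star-shaped about the
origin). Closure invariants V = n, E = 3n − 6, F = 2n − 4, V − E + F = 2
are asserted in tests up to n = 5000. Topology is frozen at the prototype:
no re-triangulation or edge flips ever happen after this stage.

## Deformation and smoothing

Radius replacement is exact: vertex k moves to radius v_k along its
original ray, so vertex norms equal the input values to machine precision.
Inputs are min–max normalized onto [0.5, 1.5] first (constant vectors map
to the midpoint). The lower bound keeps radii strictly positive — a zero
radius would collapse a vertex into the core and degenerate its faces; the
interval centers the nominal shape at radius 1.

Smoothing is the umbrella operator: x_i ← x_i + λ (mean of edge-neighbour
positions − x_i), applied synchronously to all vertices per iteration.
Defaults λ = 0.5, tolerance 10⁻³ (relative to mean radius), max 20
iterations; on realistic sizes movement is negligible after ~5 iterations.
Two guards keep the mesh valid:

* any vertex whose move would flip an incident face's normal inward
  (non-positive dot product with the face centroid direction) has its move
  halved, up to 8 times, then zeroed — so each iteration ends in a valid
  outward-oriented state;
* the face array is never modified (checked bit-identical in tests).

Known behaviour, documented rather than hidden: pure Laplacian smoothing
shrinks. On very coarse meshes (n ≲ 50) the shrinkage is self-similar, the
relative-displacement stopping rule never fires, and iteration runs to
max_iter; reported radii are then noticeably below the normalized scale.
Features remain comparable across samples because every sample is
processed identically. A `radial_only` mode smooths radii along the
neighbour graph while keeping every vertex on its ray, for strict
per-dimension interpretability. Smoothing is not volume-compensated.

Colors encode the *source* values (not the smoothed geometry):
min–max-mapped to cyan → gray → red with linear interpolation per channel;
constant input is all gray.

## Features

* COM is the unweighted mean of vertex coordinates — deliberately not an
  area- or volume-weighted centroid, matching the representation where
  each vertex stands for one dimension with equal a-priori weight.
  r = ‖COM‖.
* Surface area sums Heron's formula over faces, in Kahan's numerically
  stable arrangement (sides sorted, factored differences) so needle
  triangles do not lose precision; tests pin it against the cross-product
  area to 1e-9 relative.
* Convexity: a face's protrusion score is its centroid radius minus the
  mean centroid radius of its three edge-adjacent faces. `v` iff score
  > 0; ties (including the perfect sphere, where all scores vanish) go to
  `c` so motif strings are deterministic. This local contrast is one
  reasonable discretization of "sticks out vs caves in"; curvature-based
  alternatives can be swapped in against the same interface.
* Motif search enumerates all C(F, k) face tuples (vectorized in chunks);
  a tuple's separation accuracy is the best two-class accuracy obtainable
  by assigning each distinct motif string to its majority group. Ties go
  to the lexicographically smallest tuple. The default budget refuses
  searches beyond 500 000 tuples and advises dimensionality reduction
  (PCA, centered, unscaled — components share units) first. At the
  reference scale (36 dimensions → 68 faces, C(68,3) = 50 116 tuples,
  36 samples) the search takes well under a second on one CPU.

  Because the reported accuracy is a **maximum over tens of thousands of
  tuples**, it is biased upward under the null: two groups drawn from the
  same process score ~0.65–0.75, not 0.5 (we verified this against a
  label-permutation reference). Exactly 0.5 arises only for literally
  identical groups. Interpret the accuracy of a searched motif against a
  permutation baseline, never against 0.5.

## Silhouettes and scan profiles

Projection is orthographic (camera basis from azimuth/elevation), which
makes silhouettes scale-independent and allows an exact oracle: for a
convex mesh the silhouette equals the 2-D convex hull of the projected
vertices. Silhouette edges are those whose two incident faces face
opposite half-spaces along the view; they are chained into loops and the
largest-area loop (the outer outline) is kept, dropping occluded inner
loops. Scan profiles fire m (default 64) equally spaced parallel lines
across the outline's bounding box from a named side; each length is the
distance from the box edge to the first outline intersection (shapely
handles the segment intersections), and lines that miss the outline score
the full box extent so profiles stay numeric. Profile comparison
minimizes the overlap-normalized mean absolute difference over integer
index shifts in [−max_shift, max_shift] (ties prefer the smaller |shift|),
reporting the minimizing shift — small vertical shifts absorb alignment
differences between views.

## Rendering and serialization

Renders use a painter's-algorithm rasterizer on Pillow: faces sorted by
mean depth, filled flat with their mean vertex color scaled by a fixed
view-dependent shade; axes (pink/yellow/blue for x/y/z) and the red COM
vector are optional overlays; anaglyphs combine the red channel of a view
at azimuth −δ/2 with the green/blue channels at +δ/2 (δ default 5°).
Everything is deterministic to the byte — no fonts, no timestamps, no
backend variation.

Mesh exports: VRML 2.0 IndexedFaceSet (.wrl) with per-vertex colors,
Wavefront OBJ (1-based indices; colors as the common xyzrgb vertex-line
extension), and ascii PLY (uchar colors). Floats are written with 17
significant digits, so vertex coordinates round-trip exactly; PLY colors
round-trip to 1/255. The original tool's .wrl dialect is unknown, so
compatibility is defined by round-trip, not byte equality.

## Synthetic data

The generator emulates the bulk-transcriptomic inputs the method targets:
log-normal magnitudes (meanlog 3.0, sdlog 1.0 — median ≈ 20, right-skewed
over about a decade) low-pass filtered along the spiral index (moving
average, window n/12, circular) so plurigons show coherent hills and
valleys instead of white-noise spikes. Two-group fixtures share one
template; each sample adds independent multiplicative log-normal noise
(sdlog 0.1, i.e. ~10% CV, typical replicate noise for expression arrays),
and group B multiplies planted dimensions by their effect sizes. The
reference design is 36 dimensions, 18 + 18 samples, three single-dimension
planted regions (one per third of the index range, positions seeded),
effect ×1.5 — a desk-scale analogue of a two-genotype contrast after
dimensionality reduction. What it does not emulate: probe-level artifacts,
normalization batch effects, correlated gene modules spanning distant
spiral positions, or heavy-tailed outliers; passing tests demonstrate the
geometry and search machinery, not robustness to those real-data issues.

## Problem sizes and determinism

Tests and the acceptance script run at n up to 5000 vertices, 20-seed
smoothing ensembles at n = 500, 10⁴ random triangles, 20 random
silhouette views and the 36-dimension motif workflow; the whole suite
completes in a few seconds on one CPU. All randomness flows through
numpy's `default_rng` with explicit seeds; the acceptance script derives
every stream from its `--seed` argument, except the two-group reference
design, which is itself part of the fixed study conditions (design
seed 3).
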