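import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plurigon.errors import PlurigonError
from plurigon.features import (
    average_radius_core,
    com_magnitude,
    compute_com,
    compute_features,
    convexity_scores,
    face_convexity,
    motif_string,
    select_discriminative_faces,
    surface_area,
    triangle_area_heron,
)

from conftest import make_plurigon


class TestCenterOfMass:
    def test_symmetric_octahedron_at_origin(self, octa_plurigon):
        assert np.allclose(compute_com(octa_plurigon), 0, atol=1e-12)

    def test_unit_prototype_com_near_origin(self):
        p = make_plurigon(np.ones(1000))
        assert com_magnitude(compute_com(p)) < 0.01

    def test_enlarged_hemisphere_shifts_com(self):
        radii = np.ones(400)
        pts_z = make_plurigon(radii).mesh.vertices[:, 2]
        radii[pts_z > 0] = 2.0  # double the northern radii
        p = make_plurigon(radii)
        assert compute_com(p)[2] > 0.05

    def test_magnitude_pythagorean(self):
        assert com_magnitude((3, 4, 12)) == pytest.approx(13.0)
        assert com_magnitude((0, 0, 0)) == 0.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=100, deadline=None)
    def test_magnitude_matches_long_hand(self, seed):
        x, y, z = np.random.default_rng(seed).normal(size=3)
        assert com_magnitude((x, y, z)) == pytest.approx(
            math.sqrt(x * x + y * y + z * z), rel=1e-12
        )


class TestRadiusAndArea:
    def test_average_radius_constant(self):
        assert average_radius_core(make_plurigon(np.full(30, 2.0))) == pytest.approx(2.0)

    def test_average_radius_matches_summation_oracle(self):
        vals = np.arange(1.0, 61.0)
        p = make_plurigon(vals)
        assert average_radius_core(p) == pytest.approx(vals.sum() / 60, rel=1e-12)

    def test_heron_right_triangle(self):
        assert triangle_area_heron(3, 4, 5) == pytest.approx(6.0)

    def test_heron_degenerate_is_zero(self):
        assert triangle_area_heron(1, 2, 3) == 0.0

    def test_heron_violation_raises(self):
        with pytest.raises(ValueError):
            triangle_area_heron(1, 1, 5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None)
    def test_heron_matches_cross_product_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tri = rng.normal(size=(3, 3))
        a = np.linalg.norm(tri[1] - tri[0])
        b = np.linalg.norm(tri[2] - tri[1])
        c = np.linalg.norm(tri[0] - tri[2])
        vector_area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        assert triangle_area_heron(a, b, c) == pytest.approx(vector_area, rel=1e-9)

    def test_octahedron_area_analytic(self, octa_plurigon):
        assert surface_area(octa_plurigon) == pytest.approx(4 * math.sqrt(3))

    def test_sphere_area_convergence(self):
        p = make_plurigon(np.ones(2000))
        assert surface_area(p) == pytest.approx(4 * math.pi, rel=0.01)

    def test_scaling_covariance(self):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0.5, 2.0, 150)
        f1 = compute_features(make_plurigon(vals))
        f2 = compute_features(make_plurigon(3.0 * vals))
        assert np.allclose(np.array(f2.com), 3.0 * np.array(f1.com), atol=1e-10)
        assert f2.avg_rad_core == pytest.approx(3.0 * f1.avg_rad_core, rel=1e-10)
        assert f2.surface_area == pytest.approx(9.0 * f1.surface_area, rel=1e-9)

    def test_summary_self_consistent(self):
        f = compute_features(make_plurigon(np.random.default_rng(9).uniform(0.5, 1.5, 90)))
        assert f.r == pytest.approx(com_magnitude(f.com), abs=1e-12)


class TestConvexity:
    def test_bump_called_convex_dent_concave(self):
        radii = np.ones(200)
        radii[100] = 1.5  # planted bump
        radii[50] = 0.6  # planted dent
        p = make_plurigon(radii)
        bump_faces = [i for i, f in enumerate(p.mesh.faces) if 100 in f]
        dent_faces = [i for i, f in enumerate(p.mesh.faces) if 50 in f]
        assert all(face_convexity(p, i).call == "v" for i in bump_faces)
        assert all(face_convexity(p, i).call == "c" for i in dent_faces)

    def test_perfect_sphere_all_concave_by_tie_rule(self, octa_plurigon):
        scores = convexity_scores(octa_plurigon)
        assert np.abs(scores).max() < 1e-6
        assert all(
            face_convexity(octa_plurigon, i).call == "c"
            for i in range(octa_plurigon.mesh.n_faces)
        )

    def test_call_matches_score_sign(self):
        p = make_plurigon(np.random.default_rng(6).uniform(0.5, 1.5, 100))
        for i in (0, 10, 99):
            call = face_convexity(p, i)
            assert call.call == ("v" if call.score > 0 else "c")

    def test_invalid_face_id(self):
        p = make_plurigon(np.ones(10))
        with pytest.raises(IndexError):
            face_convexity(p, p.mesh.n_faces)


class TestMotifString:
    def test_bump_dent_bump_motif(self):
        radii = np.ones(120)
        radii[[20, 60, 90]] = [1.5, 0.6, 1.5]
        p = make_plurigon(radii)
        faces = p.mesh.faces
        trio = [
            next(i for i, f in enumerate(faces) if v in f) for v in (20, 60, 90)
        ]
        assert motif_string(p, trio) == "v-c-v"

    def test_empty_list(self):
        assert motif_string(make_plurigon(np.ones(10)), []) == ""

    def test_single_face(self):
        radii = np.ones(60)
        radii[30] = 1.5
        p = make_plurigon(radii)
        fid = next(i for i, f in enumerate(p.mesh.faces) if 30 in f)
        assert motif_string(p, [fid]) == "v"

    def test_invalid_id(self):
        with pytest.raises(IndexError):
            motif_string(make_plurigon(np.ones(10)), [999])


class TestMotifSearch:
    def _groups_with_planted_face(self, n=30, per_group=8):
        """Vertex 7 is dented in group A and bumped in group B, so its
        incident faces separate the groups perfectly."""
        rng = np.random.default_rng(12)
        ga, gb = [], []
        for _ in range(per_group):
            base = rng.uniform(0.95, 1.05, n)
            dented = base.copy()
            dented[7] *= 0.7
            ga.append(make_plurigon(dented))
            bumped = base.copy()
            bumped[7] *= 1.6
            gb.append(make_plurigon(bumped))
        return ga, gb

    def test_k1_perfect_separator(self):
        ga, gb = self._groups_with_planted_face()
        res = select_discriminative_faces(ga, gb, k=1)
        assert res.accuracy == 1.0
        # the winning face must lie in the planted vertex's influence region:
        # faces incident to vertex 7 or edge-adjacent to one of them (their
        # protrusion scores are the only ones the planted contrast moves)
        from plurigon.features import _face_adjacency

        faces = ga[0].mesh.faces
        incident = {i for i, f in enumerate(faces) if 7 in f}
        adj = _face_adjacency(faces)
        influenced = incident | {int(j) for i in incident for j in adj[i]}
        assert res.faces[0] in influenced

    def test_identical_groups_give_half(self):
        rng = np.random.default_rng(13)
        group = [make_plurigon(rng.uniform(0.8, 1.2, 24)) for _ in range(6)]
        res = select_discriminative_faces(group, group, k=2)
        assert res.accuracy == pytest.approx(0.5)

    def test_budget_exceeded_advises_reduction(self):
        ga, gb = self._groups_with_planted_face()
        with pytest.raises(PlurigonError, match="reduce dimensionality"):
            select_discriminative_faces(ga, gb, k=3, max_tuples=100)

    def test_mismatched_prototypes_rejected(self):
        from plurigon.errors import GeometryError

        a = [make_plurigon(np.ones(20))]
        b = [make_plurigon(np.ones(24))]
        with pytest.raises(GeometryError):
            select_discriminative_faces(a, b, k=1)
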