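"""Fundus selection and point-to-surface distance."""

import numpy as np
import pytest

from sulcmorph import (
    DepthOptions,
    ScalarOverlay,
    SurfaceMesh,
    compute_depth,
    isolate_sulcus,
    point_to_surface_distance,
    select_fundus,
)
from sulcmorph.depth import (
    FUNDUS_SHORTFALL,
    SIGN_CONVENTION_SUSPECT,
    points_to_surface_distances,
)
from sulcmorph.synthetic import SulcusSpec, build_box_sulcus, _flat_plate

from conftest import grid_mesh, region_from_vertex_mask


def _random_mesh(rng, n_faces):
    n = max(4, n_faces)
    verts = rng.standard_normal((n, 3)) * 4
    faces = np.array([rng.choice(n, 3, replace=False) for _ in range(n_faces)])
    return SurfaceMesh(verts, faces)


class TestPointToSurface:
    def test_flat_plate_plane_distance(self):
        plate = _flat_plate((-10, 10), (-10, 10), n=4, z=0.0)
        assert point_to_surface_distance((0, 0, -5), plate) == pytest.approx(5.0)

    def test_coincident_vertex_is_zero(self):
        plate = _flat_plate((0, 10), (0, 10), n=2, z=0.0)
        v = plate.vertices[3]
        assert point_to_surface_distance(v, plate) == pytest.approx(0.0, abs=1e-12)

    def test_tilted_triangle_closed_form(self):
        # analytic foot-of-perpendicular oracle for a single triangle
        tri = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0], [0.0, 2.0, 2.0]])
        mesh = SurfaceMesh(tri, np.array([[0, 1, 2]]))
        p = np.array([0.5, 0.5, 1.0])
        normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        normal = normal / np.linalg.norm(normal)
        foot = p - np.dot(p - tri[0], normal) * normal
        # confirm the foot lies inside the triangle (barycentric in [0,1])
        a = np.linalg.solve(
            np.column_stack([tri[1] - tri[0], tri[2] - tri[0], normal]),
            foot - tri[0],
        )
        assert 0 <= a[0] <= 1 and 0 <= a[1] <= 1 and a[0] + a[1] <= 1
        expected = abs(np.dot(p - tri[0], normal))
        assert point_to_surface_distance(p, mesh) == pytest.approx(expected, abs=1e-12)

    def test_edge_and_vertex_regions(self):
        tri = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        mesh = SurfaceMesh(tri, np.array([[0, 1, 2]]))
        # beyond vertex 1 -> vertex distance
        assert point_to_surface_distance((2, 0, 0), mesh) == pytest.approx(1.0)
        # beyond edge 0-1 -> edge distance
        assert point_to_surface_distance((0.5, -2, 0), mesh) == pytest.approx(2.0)

    def test_triangle_leq_vertex_mode(self):
        rng = np.random.default_rng(5)
        mesh = _random_mesh(rng, 60)
        pts = rng.standard_normal((40, 3)) * 5
        d_tri = points_to_surface_distances(pts, mesh, DepthOptions())
        d_ver = points_to_surface_distances(
            pts, mesh, DepthOptions(distance_mode="point-to-vertex")
        )
        assert (d_tri <= d_ver + 1e-12).all()

    def test_matches_trimesh_oracle(self):
        from trimesh.triangles import closest_point as tm_closest

        rng = np.random.default_rng(9)
        mesh = _random_mesh(rng, 400)
        pts = rng.standard_normal((25, 3)) * 5
        ours = points_to_surface_distances(pts, mesh, DepthOptions())
        tris = mesh.vertices[mesh.faces]
        for k, p in enumerate(pts):
            P = np.tile(p, (len(tris), 1))
            c = tm_closest(tris, P)
            oracle = np.linalg.norm(c - P, axis=1).min()
            assert ours[k] == pytest.approx(oracle, abs=1e-9)


class TestSelectFundus:
    def test_small_region_shortfall(self):
        mesh = grid_mesh(6)
        mask = (mesh.vertices[:, 0] <= 3) & (mesh.vertices[:, 1] <= 3)
        region = region_from_vertex_mask(mesh, mask)
        overlay = ScalarOverlay(mesh.vertices[:, 0].copy())
        fs = select_fundus(region, overlay, DepthOptions(n_fundus=100))
        assert fs.shortfall
        assert len(fs.vertex_ids) == len(region.vertex_ids) < 100

    def test_single_most_extreme_vertex(self):
        mesh = grid_mesh(4)
        region = region_from_vertex_mask(mesh, np.ones(mesh.n_vertices, bool))
        values = np.arange(mesh.n_vertices, dtype=float)
        fs = select_fundus(region, ScalarOverlay(values), DepthOptions(n_fundus=1))
        assert list(fs.vertex_ids) == [0]
        fs_hi = select_fundus(
            region,
            ScalarOverlay(values),
            DepthOptions(n_fundus=1, fundus_direction="highest"),
        )
        assert list(fs_hi.vertex_ids) == [mesh.n_vertices - 1]

    def test_generator_deepest_list_recovered(self, box_subject):
        _, (pial, annot, sulc, _, truth) = box_subject
        region = isolate_sulcus(pial, annot, truth.label_name)
        fs = select_fundus(region, sulc, DepthOptions(n_fundus=100))
        assert sorted(int(v) for v in fs.vertex_ids) == sorted(truth.deepest_vertex_ids)

    def test_tie_break_toward_smaller_vertex_id(self):
        mesh = grid_mesh(4)
        region = region_from_vertex_mask(mesh, np.ones(mesh.n_vertices, bool))
        fs = select_fundus(
            region, ScalarOverlay(np.zeros(mesh.n_vertices)), DepthOptions(n_fundus=5)
        )
        assert list(fs.vertex_ids) == [0, 1, 2, 3, 4]


class TestComputeDepth:
    def test_box_sulcus_depth(self, box_subject):
        spec, (pial, annot, sulc, outer, truth) = box_subject
        region = isolate_sulcus(pial, annot, truth.label_name)
        res = compute_depth(region, sulc, outer)
        assert res.depth == pytest.approx(truth.true_depth, abs=spec.mesh_spacing)
        assert SIGN_CONVENTION_SUSPECT not in res.flags

    def test_outer_translation_additivity(self, box_subject):
        _, (pial, annot, sulc, outer, truth) = box_subject
        region = isolate_sulcus(pial, annot, truth.label_name)
        base = compute_depth(region, sulc, outer).depth
        moved = SurfaceMesh(outer.vertices + np.array([0, 0, 3.0]), outer.faces)
        res = compute_depth(region, sulc, moved)
        assert res.depth == pytest.approx(base + 3.0, abs=1e-9)

    def test_curved_fundus_underestimates_geodesic(self):
        spec = SulcusSpec(
            true_width=3.0,
            true_depth=15.0,
            fundus_curvature=0.06,
            mesh_spacing=0.5,
            length=50.0,
        )
        pial, annot, sulc, outer, truth = build_box_sulcus(spec)
        region = isolate_sulcus(pial, annot, truth.label_name)
        res = compute_depth(region, sulc, outer)
        assert res.depth < truth.true_depth  # Euclidean underestimates geodesic
        assert res.depth == pytest.approx(truth.euclidean_fundus_depth, abs=spec.mesh_spacing)

    def test_sign_flip_detected_and_configurable(self):
        spec = SulcusSpec(
            true_width=3.0, true_depth=10.0, mesh_spacing=1.0, length=20.0,
            overlay_sign=-1,
        )
        pial, annot, sulc, outer, truth = build_box_sulcus(spec)
        region = isolate_sulcus(pial, annot, truth.label_name)
        # correct direction for a flipped overlay: highest values = deepest
        good = compute_depth(
            region, sulc, outer, DepthOptions(fundus_direction="highest")
        )
        assert good.depth == pytest.approx(10.0, abs=1.0)
        assert SIGN_CONVENTION_SUSPECT not in good.flags
        # wrong direction selects rim vertices and must warn
        bad = compute_depth(region, sulc, outer, DepthOptions(fundus_direction="lowest"))
        assert SIGN_CONVENTION_SUSPECT in bad.flags

    def test_undersized_region_flagged(self, failure_fixtures):
        import sulcmorph as sm

        sdir = failure_fixtures["undersized"]
        pial = sm.read_surface(sdir / "surf" / "lh.pial")
        outer = sm.read_surface(sdir / "surf" / "lh.pial-outer-smoothed")
        annot = sm.read_annotation(sdir / "label" / "lh.aparc.a2009s.annot")
        sulc = sm.read_overlay(sdir / "surf" / "lh.sulc", pial.n_vertices)
        region = isolate_sulcus(pial, annot, "S_central")
        res = compute_depth(region, sulc, outer)
        assert res
        assert FUNDUS_SHORTFALL in res.flags
        assert len(res.fundus.vertex_ids) == len(region.vertex_ids) < 100
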