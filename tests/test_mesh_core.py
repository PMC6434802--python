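"""Mesh data model, I/O, validation, and integral quantities."""

import itertools

import numpy as np
import pytest

from aneumorph import (
    AneurysmDome,
    CapSpec,
    TriangleSurface,
    cap_neck,
    convex_hull_metrics,
    enclosed_volume,
    make_spherical_cap,
    minimal_bounding_sphere,
    read_mesh,
    surface_area,
    validate_surface,
)
from aneumorph.mesh_core import MeshError, _signed_volume, write_mesh

from conftest import make_cube, make_square_pyramid, random_rotation


class TestTopology:
    def test_cube_is_closed_with_deduplicated_vertices(self, cube):
        assert cube.n_vertices == 8
        assert cube.n_triangles == 12
        assert cube.boundary_loops == []

    def test_open_dome_has_one_boundary_loop(self, hemisphere):
        dome, _ = hemisphere
        loops = dome.surface.boundary_loops
        assert len(loops) == 1
        # every rim vertex sits on z=0
        assert np.allclose(dome.surface.vertices[loops[0]][:, 2], 0.0, atol=1e-12)

    def test_missing_vertex_reference_raises(self):
        with pytest.raises(MeshError, match="missing vertex"):
            TriangleSurface(np.zeros((3, 3)), [[0, 1, 5]])

    def test_nonmanifold_edge_raises(self):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0.5]], dtype=float
        )
        f = [[0, 1, 2], [0, 1, 3], [0, 1, 4]]  # edge (0,1) in three triangles
        with pytest.raises(MeshError, match="non-manifold"):
            TriangleSurface(v, f)

    def test_orientation_made_consistent(self):
        cube = make_cube()
        scrambled = cube.triangles.copy()
        scrambled[::2] = scrambled[::2][:, ::-1]  # flip half the faces
        fixed = TriangleSurface(cube.vertices, scrambled)
        report = validate_surface(fixed)
        assert report.inconsistent_edges == []
        assert abs(abs(_signed_volume(fixed)) - 1.0) < 1e-12

    def test_stl_roundtrip(self, tmp_path, cube):
        path = tmp_path / "cube.stl"
        write_mesh(cube, path)
        back = read_mesh(path)
        assert back.n_vertices == 8
        assert back.is_closed
        assert abs(surface_area(back) - 6.0) < 1e-9

    def test_obj_roundtrip(self, tmp_path, hemisphere):
        dome, _ = hemisphere
        path = tmp_path / "dome.obj"
        write_mesh(dome.surface, path)
        back = read_mesh(path)
        assert len(back.boundary_loops) == 1
        assert abs(surface_area(back) - surface_area(dome.surface)) < 1e-6

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.stl"
        bad.write_text("solid nonsense\n  facet incomplete\n")
        with pytest.raises(Exception):
            read_mesh(bad)


class TestValidation:
    def test_cube_passes(self, cube):
        report = validate_surface(cube, check_self_intersections=True)
        assert report.passed
        assert report.boundary_loop_count == 0
        d = report.as_dict()
        assert d["passed"] is True

    def test_cube_with_missing_face_reports_hole(self, cube):
        holey = TriangleSurface(cube.vertices, cube.triangles[:-1])
        report = validate_surface(holey)
        assert report.boundary_loop_count == 1
        assert not holey.is_closed

    def test_interpenetrating_tetrahedra_detected(self):
        def tetra(offset):
            v = (
                np.array(
                    [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float
                )
                + offset
            )
            f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
            return v, f

        v1, f1 = tetra(np.zeros(3))
        v2, f2 = tetra(np.array([0.15, 0.15, 0.15]))
        merged = TriangleSurface(
            np.vstack([v1, v2]), np.vstack([f1, f2 + 4]), deduplicate=False
        )
        report = validate_surface(merged, check_self_intersections=True)
        assert not report.passed
        assert len(report.self_intersecting_pairs) > 0
        # brute-force all-pairs oracle (no prefilter), checked pairwise
        from aneumorph.mesh_core import _tri_tri_intersects

        corners = merged.triangle_corners
        tris = merged.triangles
        oracle = [
            (i, j)
            for i, j in itertools.combinations(range(len(tris)), 2)
            if not set(tris[i]) & set(tris[j])
            and _tri_tri_intersects(corners[i], corners[j])
        ]
        assert sorted(report.self_intersecting_pairs) == sorted(oracle)

    def test_disjoint_tetrahedra_clean(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
        merged = TriangleSurface(
            np.vstack([v, v + 5.0]), np.vstack([f, f + 4]), deduplicate=False
        )
        report = validate_surface(merged, check_self_intersections=True)
        assert report.self_intersecting_pairs == []


class TestIntegrals:
    def test_cube_area_and_volume_exact(self, cube):
        assert surface_area(cube) == pytest.approx(6.0, abs=1e-12)
        assert enclosed_volume(cube) == pytest.approx(1.0, abs=1e-12)

    def test_hemisphere_area_closed_form(self, hemisphere):
        dome, _ = hemisphere
        assert surface_area(dome.surface) == pytest.approx(2 * np.pi, rel=5e-3)

    def test_cap_area_and_volume_closed_form(self, cap54):
        dome, truth = cap54
        assert surface_area(dome.surface) == pytest.approx(truth["A"], rel=5e-3)
        closed = cap_neck(dome)
        assert closed.volume == pytest.approx(truth["V"], rel=5e-3)

    def test_open_surface_volume_raises(self, hemisphere):
        with pytest.raises(MeshError, match="watertight"):
            enclosed_volume(hemisphere[0].surface)

    def test_inward_orientation_raises(self, cube):
        with pytest.raises(MeshError, match="orientation|negative"):
            enclosed_volume(cube.flipped())

    def test_flipping_negates_signed_volume(self, cube):
        assert _signed_volume(cube.flipped()) == pytest.approx(
            -_signed_volume(cube), abs=1e-15
        )

    def test_empty_subset_warns(self, cube):
        with pytest.warns(UserWarning, match="empty"):
            area = surface_area(cube, np.zeros(12, dtype=bool))
        assert area == 0.0

    def test_volume_rigid_motion_invariant(self, cube):
        rng = np.random.default_rng(42)
        moved = cube.transformed(
            rotation=random_rotation(rng), translation=[3.0, -1.0, 2.5]
        )
        assert enclosed_volume(moved) == pytest.approx(1.0, rel=1e-12)


class TestCapNeck:
    def test_hemisphere_cap(self, hemisphere):
        dome, _ = hemisphere
        closed = cap_neck(dome)
        assert closed.surface.is_closed
        assert closed.volume == pytest.approx(2 * np.pi / 3, rel=5e-3)
        assert closed.closed_area == pytest.approx(3 * np.pi, rel=5e-3)
        # non-cap area equals the dome area exactly
        assert closed.dome_area == pytest.approx(
            surface_area(dome.surface), rel=1e-12
        )

    def test_planar_square_loop_cap_area_exact(self):
        dome = make_square_pyramid()
        closed = cap_neck(dome)
        cap_area = surface_area(closed.surface, closed.cap_triangle_mask)
        assert cap_area == pytest.approx(1.0, abs=1e-12)

    def test_nonplanar_loop_cap_exceeds_projected_area(self):
        # saddle rim: z = 0.3 cos(2 phi) on the unit circle, fan dome to apex
        n = 64
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        rim = np.column_stack(
            [np.cos(phi), np.sin(phi), 0.3 * np.cos(2 * phi)]
        )
        apex = np.array([[0.0, 0.0, 1.5]])
        v = np.vstack([rim, apex])
        f = np.array([[i, (i + 1) % n, n] for i in range(n)])
        dome = AneurysmDome(surface=TriangleSurface(v, f))
        closed = cap_neck(dome)
        assert closed.surface.is_closed
        cap_area = surface_area(closed.surface, closed.cap_triangle_mask)
        # projection of the rim onto the best-fit plane (z=0) is the unit disk
        disk = np.pi * (n / (2 * np.pi)) * np.sin(2 * np.pi / n)  # polygon area
        assert cap_area >= disk - 1e-9


class TestConvexHull:
    def test_cube_hull_exact(self, cube):
        hull_surface, area, volume = convex_hull_metrics(cube)
        assert area == pytest.approx(6.0, abs=1e-12)
        assert volume == pytest.approx(1.0, abs=1e-12)
        assert hull_surface.is_closed

    def test_hemisphere_hull_matches_closed_forms(self, hemisphere):
        dome, _ = hemisphere
        _, area, volume = convex_hull_metrics(dome.surface)
        assert area == pytest.approx(3 * np.pi, rel=5e-3)
        assert volume == pytest.approx(2 * np.pi / 3, rel=5e-3)

    def test_hull_volume_consistent_with_own_divergence_theorem(self):
        # dual route: qhull's scalar vs integral over the oriented hull mesh
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(10, 3))
        hull_surface, area, volume = convex_hull_metrics(
            TriangleSurface(pts, [[0, 1, 2]], fix_orientation=False)
        )
        assert _signed_volume(hull_surface) == pytest.approx(volume, rel=1e-12)
        assert surface_area(hull_surface) == pytest.approx(area, rel=1e-12)

    def test_all_points_inside_hull(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(40, 3))
        hull_surface, _, _ = convex_hull_metrics(
            TriangleSurface(pts, [[0, 1, 2]], fix_orientation=False)
        )
        centers = hull_surface.triangle_corners.mean(axis=1)
        normals = hull_surface.triangle_normals
        signed = (pts[:, None, :] - centers[None]) * normals[None]
        assert signed.sum(axis=2).max() < 1e-9

    def test_coplanar_points_raise(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2, np.zeros(6)])
        with pytest.raises(MeshError, match="degenerate"):
            convex_hull_metrics(TriangleSurface(pts, [[0, 1, 2]], fix_orientation=False))


def brute_force_min_sphere(points):
    """Oracle: smallest sphere over all 2/3/4-point support sets that
    encloses every point."""
    from aneumorph.mesh_core import _circumsphere

    best = (None, np.inf)
    for k in (2, 3, 4):
        for sub in itertools.combinations(range(len(points)), k):
            c, r = _circumsphere(tuple(points[list(sub)]))
            if r < 0 or r >= best[1]:
                continue
            if np.linalg.norm(points - c, axis=1).max() <= r + 1e-9:
                best = (c, r)
    return best


class TestMinimalBoundingSphere:
    def test_two_points(self):
        pts = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        center, r, area, volume = minimal_bounding_sphere(pts)
        assert np.allclose(center, [1, 0, 0], atol=1e-12)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert area == pytest.approx(4 * np.pi)
        assert volume == pytest.approx(4 * np.pi / 3)

    def test_hemisphere_supported_on_rim_and_apex(self, hemisphere):
        dome, _ = hemisphere
        center, r, area, _ = minimal_bounding_sphere(dome.surface)
        assert r == pytest.approx(1.0, rel=1e-6)
        assert np.allclose(center, [0, 0, 0], atol=1e-3)
        assert area == pytest.approx(4 * np.pi, rel=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_support_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(30, 3))
        center, r, _, _ = minimal_bounding_sphere(pts)
        oracle_center, oracle_r = brute_force_min_sphere(pts)
        assert r == pytest.approx(oracle_r, abs=1e-9)
        assert np.allclose(center, oracle_center, atol=1e-7)
        assert np.linalg.norm(pts - center, axis=1).max() <= r + 1e-9

    def test_degenerate_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 4, 9), np.zeros(9), np.zeros(9)])
        center, r, _, _ = minimal_bounding_sphere(pts)
        assert r == pytest.approx(2.0, abs=1e-9)
        assert np.allclose(center, [2, 0, 0], atol=1e-9)


class TestScalingProperties:
    @pytest.mark.parametrize("s", [2.0, 0.35])
    def test_uniform_scaling(self, cap54, s):
        dome, _ = cap54
        scaled = dome.surface.transformed(scale=s)
        assert surface_area(scaled) == pytest.approx(
            s**2 * surface_area(dome.surface), rel=1e-9
        )
        _, _, a0, v0 = minimal_bounding_sphere(dome.surface)
        _, r1, a1, v1 = minimal_bounding_sphere(scaled)
        _, r0, _, _ = minimal_bounding_sphere(dome.surface)
        assert r1 == pytest.approx(s * r0, rel=1e-9)
        _, ha0, hv0 = convex_hull_metrics(dome.surface)
        _, ha1, hv1 = convex_hull_metrics(scaled)
        assert ha1 == pytest.approx(s**2 * ha0, rel=1e-9)
        assert hv1 == pytest.approx(s**3 * hv0, rel=1e-9)

    def test_hull_and_sphere_nesting(self, cap54):
        dome, _ = cap54
        _, _, _, v_mbs = minimal_bounding_sphere(dome.surface)
        _, a_ch, v_ch = convex_hull_metrics(dome.surface)
        _, _, a_mbs, _ = minimal_bounding_sphere(dome.surface)
        assert v_ch <= v_mbs + 1e-9
        assert a_ch <= a_mbs + 1e-9

    def test_refinement_convergence(self):
        errors_a, errors_v = [], []
        for edge in (0.2, 0.1, 0.05):
            dome, truth = make_spherical_cap(CapSpec(2.0, 1.0, edge))
            closed = cap_neck(dome)
            errors_a.append(abs(closed.dome_area - truth["A"]) / truth["A"])
            errors_v.append(abs(closed.volume - truth["V"]) / truth["V"])
        assert errors_a[0] > errors_a[1] > errors_a[2]
        assert errors_v[0] > errors_v[1] > errors_v[2]
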