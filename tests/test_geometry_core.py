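"""Geometric kernel: surface I/O, plane sectioning, contours, cutting."""

import math

import numpy as np
import pytest
import trimesh

import aaamorph as am
from aaamorph.errors import (
    EmptyResultError,
    FormatError,
    NoContourError,
    ValidationError,
)


def _triangle_soup(surface):
    """Sorted per-triangle coordinates: mesh identity up to vertex merging."""
    tris = surface.vertices[surface.faces]
    tris = np.sort(tris.reshape(len(tris), -1), axis=1)
    return tris[np.lexsort(tris.T[::-1])]


class TestSurfaceIO:
    @pytest.mark.parametrize("fmt", ["stl", "ply"])
    def test_round_trip_preserves_geometry(self, cube_surface, tmp_path, fmt):
        path = tmp_path / f"cube.{fmt}"
        am.write_surface(cube_surface, str(path), fmt)
        back = am.read_surface(str(path))
        assert back.n_faces == 12
        np.testing.assert_allclose(
            _triangle_soup(back), _triangle_soup(cube_surface), atol=1e-6
        )

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.stl"
        path.write_bytes(b"")
        with pytest.raises((FormatError, OSError)):
            am.read_surface(str(path))

    def test_out_of_range_face_index_rejected_before_write(self, cube_surface, tmp_path):
        cube_surface.faces[0, 0] = 99  # mutate after construction
        with pytest.raises(ValidationError):
            am.write_surface(cube_surface, str(tmp_path / "bad.stl"), "stl")

    def test_tube_ply_round_trip_vertex_count(self, straight_tube, tmp_path):
        path = tmp_path / "tube.ply"
        am.write_surface(straight_tube, str(path), "ply")
        back = am.read_surface(str(path))
        assert back.n_vertices == straight_tube.n_vertices

    def test_too_few_faces_rejected(self):
        with pytest.raises(ValidationError):
            am.TriangleSurface(np.eye(4, 3), [[0, 1, 2]])


class TestPlaneSection:
    def test_cube_midplane_is_one_closed_square(self, cube_surface):
        contours = am.plane_section(cube_surface, am.SectionPlane([0, 0, 0], [0, 0, 1]))
        assert len(contours) == 1
        (c,) = contours
        assert c.closed
        assert am.contour_length(c) == pytest.approx(40.0, abs=1e-9)
        assert am.max_contour_diameter(c) == pytest.approx(10 * math.sqrt(2), abs=1e-9)

    def test_plane_missing_mesh_gives_empty_list(self, cube_surface):
        assert am.plane_section(cube_surface, am.SectionPlane([0, 0, 20], [0, 0, 1])) == []

    def test_cylinder_perimeter_matches_inscribed_polygon(self, straight_tube):
        contours = am.plane_section(straight_tube, am.SectionPlane([0, 0, 25.5], [0, 0, 1]))
        assert len(contours) == 1
        assert contours[0].closed
        perim = am.contour_length(contours[0])
        assert perim == pytest.approx(2 * math.pi * 10, rel=0.005)
        # exact inscribed-polygon perimeter for a ring cut between two rings
        assert perim == pytest.approx(2 * 72 * 10 * math.sin(math.pi / 72), rel=1e-6)

    def test_section_points_lie_on_plane(self, straight_tube):
        plane = am.SectionPlane([0, 1, 20], [0.2, 0.3, 0.93])
        for c in am.plane_section(straight_tube, plane):
            d = plane.signed_distance(c.points)
            assert np.abs(d).max() <= am.geometry_core.TOL_PLANE

    def test_watertight_mesh_yields_only_closed_contours(self, cube_surface):
        for z in (-4.0, -1.3, 0.7, 4.9):
            for c in am.plane_section(cube_surface, am.SectionPlane([0, 0, z], [0.1, 0.1, 1])):
                assert c.closed

    def test_open_mesh_yields_open_rim_chains(self, cube_surface):
        half = am.cut_surface_by_plane(
            cube_surface, am.SectionPlane([0, 0, 0], [1, 0, 0]), "positive"
        )
        # a plane through the open cut rim produces an open chain
        contours = am.plane_section(half, am.SectionPlane([0, 0, 0], [0, 0, 1]))
        assert any(not c.closed for c in contours)


class TestContourMeasures:
    def _square(self, side=1.0):
        pts = np.array([[0, 0, 0], [side, 0, 0], [side, side, 0], [0, side, 0]], float)
        return am.PlanarContour(pts, True, am.SectionPlane([0, 0, 0], [0, 0, 1]))

    def test_closed_square_lengths(self):
        assert am.contour_length(self._square(1.0)) == pytest.approx(4.0)
        assert am.contour_length(self._square(10.0)) == pytest.approx(40.0)

    def test_open_polyline_length(self):
        c = am.PlanarContour([[0, 0, 0], [3, 4, 0]], False, am.SectionPlane([0, 0, 0], [0, 0, 1]))
        assert am.contour_length(c) == pytest.approx(5.0)

    def test_length_invariant_under_cyclic_rotation(self):
        sq = self._square(10.0)
        rolled = am.PlanarContour(np.roll(sq.points, 2, axis=0), True, sq.plane)
        assert am.contour_length(rolled) == pytest.approx(am.contour_length(sq))

    def test_longest_contour_selection_and_tie_break(self):
        small = self._square(3.0)
        big = self._square(10.0)
        assert am.longest_contour([big, small]) is big
        assert am.longest_contour([small, big]) is big
        # ties break to the lowest index
        twin = self._square(10.0)
        assert am.longest_contour([big, twin]) is big

    def test_longest_contour_empty_list_raises(self):
        with pytest.raises(NoContourError):
            am.longest_contour([])

    def test_diameter_of_square_is_diagonal(self):
        assert am.max_contour_diameter(self._square(10.0)) == pytest.approx(10 * math.sqrt(2))

    def test_diameter_two_point_contour(self):
        c = am.PlanarContour([[0, 0, 0], [0, 0, 7]], False, am.SectionPlane([0, 0, 0], [1, 0, 0]))
        assert am.max_contour_diameter(c) == pytest.approx(7.0)

    def test_diameter_of_regular_72gon(self):
        phi = 2 * np.pi * np.arange(72) / 72
        pts = np.column_stack([10 * np.cos(phi), 10 * np.sin(phi), np.zeros(72)])
        c = am.PlanarContour(pts, True, am.SectionPlane([0, 0, 0], [0, 0, 1]))
        d = am.max_contour_diameter(c)
        assert d == pytest.approx(20.0, rel=0.005)
        # even vertex count: antipodal vertices are a true diameter
        assert d == pytest.approx(20.0, abs=1e-9)

    def test_diameter_matches_brute_force_on_random_contours(self, rng):
        from scipy.spatial.distance import pdist

        for _ in range(100):
            n = rng.integers(3, 120)
            plane = am.SectionPlane(rng.normal(size=3), rng.normal(size=3))
            u, w = am.geometry_core._plane_basis(plane.normal)
            xy = rng.normal(scale=20, size=(n, 2))
            pts = plane.origin + xy[:, :1] * u + xy[:, 1:] * w
            c = am.PlanarContour(pts, False, plane)
            assert am.max_contour_diameter(c) == pytest.approx(
                float(pdist(pts).max()), abs=1e-9
            )


class TestCutSurface:
    def test_half_cube_bounding_box(self, cube_surface):
        half = am.cut_surface_by_plane(
            cube_surface, am.SectionPlane([0, 0, 0], [0, 0, 1]), "positive"
        )
        np.testing.assert_allclose(half.bounds()[:, 2], [0.0, 5.0], atol=1e-6)

    def test_plane_below_mesh_keeps_everything(self, cube_surface):
        out = am.cut_surface_by_plane(
            cube_surface, am.SectionPlane([0, 0, -20], [0, 0, 1]), "positive"
        )
        np.testing.assert_allclose(
            _triangle_soup(out), _triangle_soup(cube_surface), atol=1e-12
        )

    def test_plane_above_mesh_is_empty_result(self, cube_surface):
        with pytest.raises(EmptyResultError):
            am.cut_surface_by_plane(
                cube_surface, am.SectionPlane([0, 0, 20], [0, 0, 1]), "positive"
            )

    def test_cut_areas_are_additive(self, straight_tube, rng):
        total = straight_tube.area()
        for _ in range(5):
            plane = am.SectionPlane([0, 0, rng.uniform(5, 45)], rng.normal(size=3))
            pos = am.cut_surface_by_plane(straight_tube, plane, "positive").area()
            neg = am.cut_surface_by_plane(straight_tube, plane, "negative").area()
            assert pos + neg == pytest.approx(total, rel=1e-6)


class TestAgainstTrimeshSectioning:
    def test_total_section_length_matches_trimesh(self, straight_tube):
        """Independent cross-check of the intersection kernel."""
        plane_origin, plane_normal = np.array([0.0, 0.0, 20.3]), np.array([0.1, 0.2, 1.0])
        plane_normal = plane_normal / np.linalg.norm(plane_normal)
        mesh = straight_tube.to_trimesh()
        segs = trimesh.intersections.mesh_plane(mesh, plane_normal, plane_origin)
        ref_total = np.linalg.norm(segs[:, 0] - segs[:, 1], axis=1).sum()
        contours = am.plane_section(straight_tube, am.SectionPlane(plane_origin, plane_normal))
        total = sum(am.contour_length(c) for c in contours)
        assert total == pytest.approx(ref_total, rel=1e-9)
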