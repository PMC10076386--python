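import logging
import math

import numpy as np
import pytest
import trimesh
from hypothesis import given, strategies as st

from torsometrics import (
    Contour,
    CuboidROI,
    SectionPlane,
    SphericalROI,
    TorsoMesh,
    contour_centroid,
    cross_section,
    extreme_point,
    slice_extremes,
)
from torsometrics.exceptions import (
    DegenerateContourError,
    EmptyROIError,
    InsufficientOverlapError,
)


@pytest.fixture(scope="module")
def sphere_mesh():
    tm = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
    return TorsoMesh(tm.vertices, tm.faces)


@pytest.fixture(scope="module")
def cube_mesh():
    """Axis-aligned cube spanning 0..100 mm on every axis."""
    tm = trimesh.creation.box(extents=[100.0] * 3)
    return TorsoMesh(np.asarray(tm.vertices) + 50.0, tm.faces)


def _walls_mesh(z_ranges=((0.0, 100.0),)):
    """Two parallel vertical rectangles: left wall at y=20, right at y=0.

    Left wall spans x in [10, 30], right wall x in [-30, -10]; each wall
    is one rectangle (two triangles) per z range.
    """
    vertices, faces = [], []
    for x0, x1, y in ((10.0, 30.0, 20.0), (-30.0, -10.0, 0.0)):
        for z0, z1 in z_ranges:
            base = len(vertices)
            vertices += [[x0, y, z0], [x1, y, z0], [x1, y, z1], [x0, y, z1]]
            faces += [[base, base + 1, base + 2], [base, base + 2, base + 3]]
    return TorsoMesh(vertices, faces)


_WALL_BOXES = (
    CuboidROI(center=(20, 10, 50), half_extents=(15, 15, 50)),
    CuboidROI(center=(-20, 10, 50), half_extents=(15, 15, 50)),
)


class TestROITypes:
    def test_sphere_positivity(self):
        with pytest.raises(ValueError):
            SphericalROI(center=(0, 0, 0), radius=0.0)

    def test_box_positivity(self):
        with pytest.raises(ValueError):
            CuboidROI(center=(0, 0, 0), half_extents=(1, 0, 1))

    def test_plane_finite(self):
        with pytest.raises(ValueError):
            SectionPlane(float("inf"))


class TestExtremePoint:
    def test_sphere_pole(self, sphere_mesh):
        """The most superior point near the pole of a sphere is the pole."""
        roi = SphericalROI(center=(0, 0, 100), radius=30.0)
        p = extreme_point(sphere_mesh, roi, (0, 0, 1))
        assert np.linalg.norm(p - [0, 0, 100]) < 5.0  # mesh resolution

    def test_empty_roi_error_names_roi(self, sphere_mesh):
        roi = SphericalROI(center=(500, 500, 500), radius=1.0, label="hip.left")
        with pytest.raises(EmptyROIError, match="hip.left"):
            extreme_point(sphere_mesh, roi, (0, 0, 1))

    def test_tie_break_larger_abs_x_then_smaller_z(self):
        # four vertices with identical y: ties resolved deterministically
        mesh = TorsoMesh(
            [[1, 5, 0], [-3, 5, 2], [3, 5, 2], [3, 5, 1], [0, 0, 0]],
            [[0, 1, 2], [2, 3, 4]],
        )
        roi = SphericalROI(center=(0, 4, 1), radius=10.0)
        p = extreme_point(mesh, roi, (0, 1, 0))
        assert tuple(p) == (3, 5, 1)  # |x|=3 beats 1; z=1 beats z=2

    def test_vertex_permutation_invariance(self, sphere_mesh, rng):
        roi = SphericalROI(center=(0, 0, 100), radius=30.0)
        direction = (0.2, -0.3, 0.93)
        p0 = extreme_point(sphere_mesh, roi, direction)
        perm = rng.permutation(sphere_mesh.n_vertices)
        inverse = np.empty_like(perm)
        inverse[perm] = np.arange(len(perm))
        shuffled = TorsoMesh(
            sphere_mesh.vertices[perm], inverse[sphere_mesh.faces]
        )
        p1 = extreme_point(shuffled, roi, direction)
        assert np.array_equal(p0, p1)


class TestCrossSection:
    def test_cube_square_contour(self, cube_mesh):
        contours = cross_section(cube_mesh, SectionPlane(50.0))
        assert len(contours) == 1
        c = contours[0]
        assert not c.chord_closed
        assert c.perimeter == pytest.approx(400.0, abs=1e-9)
        assert c.area == pytest.approx(10000.0, abs=1e-6)

    def test_cylinder_perimeter_close_to_circle(self):
        tm = trimesh.creation.cylinder(radius=50.0, height=100.0, sections=360)
        mesh = TorsoMesh(tm.vertices, tm.faces)
        contours = cross_section(mesh, SectionPlane(0.0))
        assert len(contours) == 1
        expected = 2 * math.pi * 50.0
        assert abs(contours[0].perimeter - expected) / expected < 1e-3

    def test_plane_misses_mesh(self, cube_mesh):
        assert cross_section(cube_mesh, SectionPlane(-1000.0)) == []

    def test_open_chain_chord_closed_and_flagged(self, caplog):
        # half-cylinder shell: plane section is an open arc
        tm = trimesh.creation.cylinder(radius=50.0, height=100.0, sections=64)
        keep = np.asarray(tm.vertices)[tm.faces][:, :, 0].mean(axis=1) > 0
        half = trimesh.Trimesh(tm.vertices, tm.faces[keep], process=False)
        mesh = TorsoMesh(half.vertices, half.faces)
        with caplog.at_level(logging.WARNING):
            contours = cross_section(mesh, SectionPlane(0.0))
        assert contours and contours[0].chord_closed
        assert any("chord" in r.message for r in caplog.records)

    def test_tessellation_refinement_stable_area(self):
        """Section area of a smooth shape is tessellation-stable to 1%."""
        areas = []
        for sections in (90, 360):
            tm = trimesh.creation.cylinder(radius=50.0, height=100.0, sections=sections)
            contours = cross_section(TorsoMesh(tm.vertices, tm.faces), SectionPlane(0.0))
            areas.append(contours[0].area)
        assert abs(areas[1] - areas[0]) / areas[1] < 0.01


class TestContourCentroid:
    def test_square(self):
        c = Contour([[0, 0, 5], [100, 0, 5], [100, 100, 5], [0, 100, 5]], 5.0)
        assert np.allclose(contour_centroid(c), [50, 50, 5])

    def test_l_shape_area_centroid_not_vertex_mean(self):
        """Centroid of the L-hexagon is the area moment (5/6, 5/6), which
        differs from the vertex mean (1, 1)."""
        pts = [[0, 0, 0], [2, 0, 0], [2, 1, 0], [1, 1, 0], [1, 2, 0], [0, 2, 0]]
        c = contour_centroid(Contour(pts, 0.0))
        assert np.allclose(c, [5.0 / 6.0, 5.0 / 6.0, 0.0], atol=1e-12)

    def test_circle_symmetry(self):
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        pts = np.column_stack(
            [7.0 + 30 * np.cos(theta), -3.0 + 30 * np.sin(theta), np.full(256, 2.0)]
        )
        assert np.allclose(contour_centroid(Contour(pts, 2.0)), [7.0, -3.0, 2.0], atol=1e-6)

    def test_degenerate_contour(self):
        with pytest.raises(DegenerateContourError):
            contour_centroid(Contour([[0, 0, 0], [1, 0, 0], [2, 0, 0]], 0.0))


class TestSliceExtremes:
    def test_parallel_walls_levels_and_values(self):
        mesh = _walls_mesh()
        levels = slice_extremes(mesh, *_WALL_BOXES, step=1.0)
        assert abs(len(levels) - 101) <= 1
        for _, lp, rp in levels:
            assert lp[1] == pytest.approx(20.0, abs=1e-9)
            assert rp[1] == pytest.approx(0.0, abs=1e-9)

    def test_coarse_step(self):
        mesh = _walls_mesh()
        levels = slice_extremes(mesh, *_WALL_BOXES, step=10.0)
        assert abs(len(levels) - 11) <= 1
        assert all(lp[1] == 20.0 and rp[1] == 0.0 for _, lp, rp in levels)

    def test_gap_levels_skipped(self):
        mesh = _walls_mesh(z_ranges=((0.0, 40.0), (60.0, 100.0)))
        levels = slice_extremes(mesh, *_WALL_BOXES, step=1.0)
        zs = np.array([z for z, _, _ in levels])
        assert not ((zs > 40.5) & (zs < 59.5)).any()
        assert len(levels) > 50

    def test_nested_step_grids_share_levels(self):
        mesh = _walls_mesh()
        z1 = {z for z, _, _ in slice_extremes(mesh, *_WALL_BOXES, step=1.0)}
        z2 = {z for z, _, _ in slice_extremes(mesh, *_WALL_BOXES, step=2.0)}
        assert z2 <= z1

    def test_insufficient_overlap(self):
        mesh = _walls_mesh()
        far = CuboidROI(center=(20, 10, 500), half_extents=(15, 15, 20))
        with pytest.raises(InsufficientOverlapError):
            slice_extremes(mesh, far, _WALL_BOXES[1], step=1.0)

    def test_step_positive(self):
        with pytest.raises(ValueError):
            slice_extremes(_walls_mesh(), *_WALL_BOXES, step=0.0)


@given(
    x=st.floats(-200, 200),
    y=st.floats(-200, 200),
    z=st.floats(-200, 200),
)
def test_sphere_containment_matches_distance(x, y, z):
    """Point-in-sphere agrees with the Euclidean distance definition."""
    roi = SphericalROI(center=(10.0, -20.0, 30.0), radius=50.0)
    inside = bool(roi.contains(np.array([[x, y, z]]))[0])
    dist = math.dist((x, y, z), roi.center)
    assert inside == (dist <= roi.radius)
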