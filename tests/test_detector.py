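import numpy as np
import pytest

from dxt.detector import (
    Detector,
    Panel,
    PanelGroup,
    RayOutsidePlane,
    SingularGeometryError,
    flatten_hierarchy,
)
from dxt.geometry import Beam, GeometryError, rotation_about_axis, unit

from .conftest import make_random_panel, make_standard_panel, ray_to_panel_point


class TestPanelDMatrix:
    def test_columns_are_basis_vectors_and_origin(self, standard_panel):
        d = standard_panel.d_matrix
        assert d[:, 0] == pytest.approx((1, 0, 0))
        assert d[:, 1] == pytest.approx((0, -1, 0))
        assert d[:, 2] == pytest.approx((-50, 50, 200))

    def test_determinant_by_cofactor_expansion(self, standard_panel):
        # expansion along the third column: 200 * (1*(-1) - 0) = -200
        assert np.linalg.det(standard_panel.d_matrix) == pytest.approx(-200.0)

    def test_origin_in_plane_span_is_singular(self):
        panel = make_standard_panel(
            fast_axis=(1, 0, 0), slow_axis=(0, 1, 0), origin=(1, 1, 0)
        )
        with pytest.raises(SingularGeometryError):
            panel.ray_intersect((0, 0, 1))

    def test_orthogonality_enforced_not_repaired(self):
        with pytest.raises(GeometryError):
            make_standard_panel(fast_axis=(1, 0, 0), slow_axis=unit((0.1, -1, 0)))


class TestLabCoord:
    def test_corner_is_origin(self, standard_panel):
        assert standard_panel.lab_coord((0, 0)) == pytest.approx(standard_panel.origin)

    def test_componentwise(self, standard_panel):
        assert standard_panel.lab_coord((10, 20)) == pytest.approx((-40, 30, 200))

    def test_equals_d_matrix_product(self, rng):
        for _ in range(50):
            panel = make_random_panel(rng)
            xy = rng.uniform(-30, 130, size=2)
            expected = panel.d_matrix @ np.array([xy[0], xy[1], 1.0])
            assert panel.lab_coord(xy) == pytest.approx(expected, abs=1e-12)


class TestRayIntersect:
    def test_direct_beam_centre(self, standard_panel):
        xy, inside = standard_panel.ray_intersect((0, 0, 1))
        assert xy == pytest.approx((50, 50), abs=1e-12)
        assert inside

    def test_oblique_ray_by_linear_solve(self, standard_panel):
        # lambda*(0.1, 0, 1) = origin + x*fast + y*slow: lambda = 200 from z,
        # x = 20 + 50 from the fast component
        xy, inside = standard_panel.ray_intersect(unit((0.1, 0, 1)))
        assert xy == pytest.approx((70, 50), abs=1e-9)
        assert inside

    def test_backwards_ray_rejected(self, standard_panel):
        with pytest.raises(RayOutsidePlane):
            standard_panel.ray_intersect((0, 0, -1))

    def test_parallel_ray_rejected(self, standard_panel):
        with pytest.raises(RayOutsidePlane):
            standard_panel.ray_intersect((1, 0, 0))

    def test_round_trip_recovers_panel_point(self, rng):
        """Projecting the ray through a known panel point must recover it."""
        for _ in range(200):
            panel = make_random_panel(rng)
            xy = rng.uniform(0, 100, size=2)
            s = ray_to_panel_point(panel, xy)
            got, inside = panel.ray_intersect(s)
            assert got == pytest.approx(tuple(xy), abs=1e-6)
            assert inside

    def test_result_position_collinear_with_ray(self, rng):
        for _ in range(100):
            panel = make_random_panel(rng)
            s = ray_to_panel_point(panel, rng.uniform(0, 100, size=2))
            xy, _ = panel.ray_intersect(s)
            pos = panel.lab_coord(xy)
            assert np.linalg.norm(np.cross(pos, s)) <= 1e-9 * np.linalg.norm(pos)


class TestDetector:
    def test_single_panel_direct_beam(self, standard_panel):
        det = Detector([standard_panel])
        hit = det.ray_intersect((0, 0, 1))
        assert hit.panel_id == 0
        assert hit.xy == pytest.approx((50, 50), abs=1e-12)

    def test_two_panel_tiling_selects_correct_panel(self):
        # two coplanar 100x100 mm panels tiling x<0 and x>0 at z=200
        left = make_standard_panel(name="left", origin=(-100, 50, 200))
        right = make_standard_panel(name="right", origin=(0, 50, 200))
        det = Detector([left, right])
        hit = det.ray_intersect(unit((50, 0, 200)))
        assert hit.panel_id == 1
        # per-panel oracle: same ray on the right panel alone
        xy, inside = right.ray_intersect(unit((50, 0, 200)))
        assert inside and hit.xy == pytest.approx(xy)

    def test_gap_between_panels_gives_no_hit(self):
        left = make_standard_panel(name="left", origin=(-110, 50, 200))
        right = make_standard_panel(name="right", origin=(10, 50, 200))
        det = Detector([left, right])
        assert det.ray_intersect((0, 0, 1)) is None

    def test_overlapping_panels_lowest_id_wins(self):
        a = make_standard_panel(name="a")
        b = make_standard_panel(name="b", origin=(-50, 50, 210))
        det = Detector([a, b])
        assert det.ray_intersect((0, 0, 1)).panel_id == 0

    def test_beam_centre_matches_header_geometry(self):
        panel = make_standard_panel(origin=(-94, 94, 150), image_size=(2048, 2048))
        det = Detector([panel])
        hit = det.beam_centre(Beam((0, 0, 1), 0.9795))
        assert hit.panel_id == 0
        assert hit.xy == pytest.approx((94, 94), abs=1e-12)

    def test_beam_centre_after_two_theta_rotation(self, rng):
        """Rotating the whole panel frame about x moves the beam centre as
        predicted by an independent linear solve."""
        R = rotation_about_axis((1, 0, 0), -30.0)
        base = make_standard_panel()
        panel = make_standard_panel(
            fast_axis=R @ base.fast_axis,
            slow_axis=R @ base.slow_axis,
            origin=R @ base.origin,
        )
        xy, inside = panel.ray_intersect((0.0, 0.0, 1.0))
        # oracle: solve x*f + y*s - lam*beam = -origin
        M = np.column_stack([panel.fast_axis, panel.slow_axis, -np.array([0.0, 0.0, 1.0])])
        x, y, lam = np.linalg.solve(M, -panel.origin)
        assert lam > 0
        assert xy == pytest.approx((x, y), abs=1e-9)
        # the tilted beam centre walks off this panel's 100 mm extent,
        # so the detector-level lookup reports no hit
        assert Detector([panel]).beam_centre(Beam((0, 0, 1), 1.0)) is None

    def test_rigid_motion_equivariance(self, rng):
        """Rotating beam and detector together leaves plane coords unchanged."""
        for _ in range(20):
            panel = make_random_panel(rng)
            s = ray_to_panel_point(panel, rng.uniform(10, 90, size=2))
            xy0, _ = panel.ray_intersect(s)
            from .conftest import random_rotation

            R = random_rotation(rng)
            moved = make_standard_panel(
                fast_axis=R @ panel.fast_axis,
                slow_axis=R @ panel.slow_axis,
                origin=R @ panel.origin,
            )
            xy1, _ = moved.ray_intersect(R @ s)
            assert xy1 == pytest.approx(xy0, abs=1e-9)


class TestHierarchy:
    def test_identity_group_leaves_panel_unchanged(self, standard_panel):
        root = PanelGroup(children=[standard_panel])
        det = flatten_hierarchy(root)
        assert len(det) == 1
        assert det[0] == standard_panel

    def test_chain_of_identity_groups_is_exact(self, standard_panel):
        root = PanelGroup(children=[PanelGroup(children=[PanelGroup(children=[standard_panel])])])
        det = flatten_hierarchy(root)
        assert np.array_equal(det[0].fast_axis, standard_panel.fast_axis)
        assert np.array_equal(det[0].slow_axis, standard_panel.slow_axis)
        assert np.array_equal(det[0].origin, standard_panel.origin)

    def test_rotated_group_frame(self):
        # group frame rotated 90 deg about z: local fast maps to lab (0,1,0)
        panel = Panel(
            fast_axis=(1, 0, 0), slow_axis=(0, -1, 0), origin=(0, 0, 100),
            pixel_size=(0.1, 0.1), image_size=(100, 100),
        )
        group = PanelGroup(fast_axis=(0, 1, 0), slow_axis=(-1, 0, 0), children=[panel])
        det = flatten_hierarchy(group)
        R = rotation_about_axis((0, 0, 1), 90.0)
        assert det[0].fast_axis == pytest.approx((0, 1, 0), abs=1e-12)
        assert det[0].origin == pytest.approx(R @ (0, 0, 100), abs=1e-12)

    def test_nested_translations_compose(self, standard_panel):
        inner = PanelGroup(origin=(10, 0, 0), children=[standard_panel])
        root = PanelGroup(origin=(0, 0, 50), children=[inner])
        det = flatten_hierarchy(root)
        assert det[0].origin == pytest.approx(standard_panel.origin + (10, 0, 50))

    def test_depth_first_leaf_order(self, standard_panel):
        p1 = make_standard_panel(name="p1")
        p2 = make_standard_panel(name="p2")
        p3 = make_standard_panel(name="p3")
        root = PanelGroup(children=[PanelGroup(children=[p1, p2]), p3])
        det = flatten_hierarchy(root)
        assert [p.name for p in det] == ["p1", "p2", "p3"]

    def test_shared_node_rejected(self, standard_panel):
        shared = PanelGroup(children=[standard_panel])
        root = PanelGroup(children=[shared, shared])
        with pytest.raises(GeometryError):
            flatten_hierarchy(root)


def test_detector_requires_a_panel():
    with pytest.raises(GeometryError):
        Detector([])
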