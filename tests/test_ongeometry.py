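import numpy as np
import pytest

from onstrain import ongeometry as og
from onstrain.transforms import RigidTransform


def _tube(n=8000, radius=1.5, length=26.0, bow=0.0, seed=0):
    """Solid tube cloud along -Z with optional sine bow in X."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, length, n)
    th = rng.uniform(0, 2 * np.pi, n)
    r = radius * np.sqrt(rng.uniform(size=n))
    x = bow * np.sin(np.pi * z / length) + r * np.cos(th)
    y = r * np.sin(th)
    return np.c_[x, y, -z]


class TestCentroids:
    def test_straight_tube_centroids_collinear(self):
        cents = og.on_centroids(_tube(), long_axis=[0, 0, -1], bin_width=1.0)
        # centroids lie on the tube axis to within noise/sqrt(n)
        assert np.abs(cents[:, 0]).max() < 0.15
        assert np.abs(cents[:, 1]).max() < 0.15

    def test_bowed_tube_tracks_axis(self):
        cents = og.on_centroids(_tube(bow=2.0), long_axis=[0, 0, -1], bin_width=1.0)
        expect = 2.0 * np.sin(np.pi * (-cents[:, 2]) / 26.0)
        assert np.abs(cents[:, 0] - expect).max() < 0.25

    def test_sparse_bin_merged_with_warning(self, caplog):
        import logging

        pts = np.vstack([_tube(2000), [[0, 0, -30.0]]])  # lone straggler
        with caplog.at_level(logging.WARNING, logger="onstrain.ongeometry"):
            cents = og.on_centroids(pts, long_axis=[0, 0, -1], bin_width=1.0,
                                    min_points=5)
        assert any("merg" in r.message for r in caplog.records)
        assert len(cents) <= 31

    def test_empty_cloud_errors(self):
        with pytest.raises(ValueError):
            og.on_centroids(np.empty((0, 3)))


class TestJunction:
    def _sphere(self, n=6000, r=12.0, seed=0):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(n, 3))
        return r * p / np.linalg.norm(p, axis=1, keepdims=True)

    def test_axis_aligned_construction(self):
        globe = self._sphere()
        cents = np.array([[0, 0, -14.0], [0, 0, -16.0], [0, 0, -18.0]])
        j, t = og.find_on_junction(globe, cents)
        assert np.linalg.norm(j - [0, 0, -12.0]) < 0.1
        assert t @ [0, 0, -1] > 0.99

    def test_sphere_surface_mode_matches(self):
        globe = self._sphere()
        cents = np.array([[0, 0, -14.0], [0, 0, -16.0], [0, 0, -18.0]])
        j, t = og.find_on_junction(globe, cents, surface="sphere")
        assert np.linalg.norm(j - [0, 0, -12.0]) < 0.05
        assert t @ [0, 0, -1] > 0.999

    def test_miss_reports_distance(self):
        globe = self._sphere()
        cents = np.array([[40, 0, -14.0], [40, 0, -16.0]])
        with pytest.raises(ValueError, match="misses"):
            og.find_on_junction(globe, cents)


class TestPseudoApex:
    def _cone_wall(self, vertex, axis, half_angle=25.0, n=6000, seed=0):
        rng = np.random.default_rng(seed)
        axis = np.asarray(axis, float)
        axis /= np.linalg.norm(axis)
        u = np.cross(axis, [0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(axis, u)
        h = rng.uniform(3, 40, n)
        ang = rng.uniform(0, 2 * np.pi, n)
        r = h * np.tan(np.deg2rad(half_angle))
        return (np.asarray(vertex) + np.outer(h, axis)
                + r[:, None] * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))

    def test_line_through_axis_hits_vertex(self):
        vertex = np.array([-5.0, 0.0, -37.0])
        axis = np.array([0.1, 0.0, 1.0])
        wall = self._cone_wall(vertex, axis)
        p = vertex + 30 * axis / np.linalg.norm(axis)
        apex = og.find_pseudo_apex(p, -axis, wall)
        assert np.linalg.norm(apex - vertex) < 0.3

    def test_off_axis_line_recovers_vertex_region(self):
        vertex = np.array([-5.0, 0.0, -37.0])
        axis = np.array([0.12, 0.0, 0.99])
        wall = self._cone_wall(vertex, axis)
        p = vertex + np.array([3.0, 0.5, 30.0])
        d = vertex + np.array([0.5, 0.0, 1.0]) - p
        apex = og.find_pseudo_apex(p, d / np.linalg.norm(d), wall)
        assert np.linalg.norm(apex - vertex) < 1.0

    def test_bad_cone_fit_errors(self, rng):
        blob = rng.normal(size=(500, 3)) * 10
        with pytest.raises(ValueError):
            og.find_pseudo_apex([0, 0, 0], [0, 0, -1.0], blob)


class TestCurveFit:
    def test_collinear_knots_give_straight_segment(self):
        t = np.linspace(0, 1, 12)
        knots = np.outer(t, [1.0, 2.0, -3.0])
        path = og.fit_on_curve(knots)
        assert path.length == pytest.approx(np.linalg.norm(knots[-1] - knots[0]),
                                            abs=1e-6)
        assert og.tortuosity(path) == pytest.approx(1.0, abs=1e-6)

    def test_cubic_polynomial_reproduced_exactly(self):
        t = np.linspace(0, 1, 20)
        knots = np.c_[t**3 - 0.5 * t, t**2, t]
        path = og.fit_on_curve(knots)
        dense = path.spline(np.linspace(0, 1, 400))
        td = np.linspace(0, 1, 4000)
        truth = np.c_[td**3 - 0.5 * td, td**2, td]
        from scipy.spatial import cKDTree

        assert cKDTree(truth).query(dense)[0].max() < 1e-3

    def test_quarter_circle_arc_length(self):
        R = 20.0
        th = np.linspace(0, np.pi / 2, 25)
        knots = np.c_[R * np.cos(th), R * np.sin(th), np.zeros_like(th)]
        path = og.fit_on_curve(knots)
        assert path.length == pytest.approx(np.pi / 2 * R, rel=1e-3)

    def test_semicircle_tortuosity(self):
        th = np.linspace(0, np.pi, 41)
        knots = np.c_[10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)]
        path = og.fit_on_curve(knots)
        assert og.tortuosity(path) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_tortuosity_invariant_to_rigid_motion_and_scale(self):
        th = np.linspace(0, np.pi / 2, 20)
        knots = np.c_[10 * np.cos(th), 10 * np.sin(th), np.zeros_like(th)]
        tort0 = og.tortuosity(og.fit_on_curve(knots))
        T = RigidTransform.from_axis_angle([1, 2, 3], 40.0, translation=[4, 5, 6])
        tort1 = og.tortuosity(og.fit_on_curve(T.apply(knots)))
        tort2 = og.tortuosity(og.fit_on_curve(knots * 3.0))
        assert tort1 == pytest.approx(tort0, abs=1e-6)
        assert tort2 == pytest.approx(tort0, abs=1e-6)


class TestLocalFramesAndSections:
    def test_straight_path_keeps_junction_x(self):
        knots = np.outer(np.linspace(0, 26, 12), [0, 0, -1.0])
        path = og.fit_on_curve(knots)
        frames = og.local_frames_along_path(path, [1, 0, 0], np.linspace(0.1, 0.9, 9))
        for fr in frames:
            assert np.allclose(fr.X, [1, 0, 0], atol=1e-6)
            assert np.linalg.det(fr.axes) == pytest.approx(1.0, abs=1e-9)

    def test_quarter_circle_frames_follow_tangent_without_flips(self):
        th = np.linspace(0, np.pi / 2, 30)
        knots = np.c_[np.zeros_like(th), 20 * np.sin(th), -20 * (1 - np.cos(th))]
        path = og.fit_on_curve(knots)
        frames = og.local_frames_along_path(path, [1, 0, 0], np.linspace(0.05, 0.95, 19))
        xs = np.array([fr.X for fr in frames])
        assert np.all(np.einsum("ij,ij->i", xs[:-1], xs[1:]) > 0)

    def test_helical_path_x_is_projection_of_fixed_vector(self):
        t = np.linspace(0, 1, 40)
        knots = np.c_[0.9 * np.cos(2 * np.pi * t), 0.9 * np.sin(2 * np.pi * t), -26 * t]
        path = og.fit_on_curve(knots)
        s_vals = np.linspace(0.1, 0.9, 9)
        frames = og.local_frames_along_path(path, [1, 0, 0], s_vals)
        for s, fr in zip(s_vals, frames):
            Z = path.tangent(float(s))
            proj = np.array([1.0, 0, 0]) - ([1.0, 0, 0] @ Z) * Z
            proj /= np.linalg.norm(proj)
            assert np.allclose(fr.X, proj, atol=1e-9)

    def test_cylinder_sections_radius_and_area(self):
        pts = _tube(20000, radius=1.5)
        knots = np.outer(np.linspace(0, 26, 12), [0, 0, -1.0])
        path = og.fit_on_curve(knots)
        secs = og.cross_sections(path, pts, n_sections=20, n_angles=36,
                                 junction_x=[1, 0, 0])
        valid = [s for s in secs if s.valid]
        assert len(valid) >= 18
        for sec in valid:
            assert np.all(np.abs(sec.r - 1.5) < 0.15)
            assert sec.area == pytest.approx(np.pi * 1.5**2, rel=0.05)

    def test_bent_tube_sections_stay_circular(self):
        # quarter-torus: planes follow the tangent, sections remain circular
        R, r = 20.0, 1.5
        rng = np.random.default_rng(0)
        th = rng.uniform(0, np.pi / 2, 30000)
        phi = rng.uniform(0, 2 * np.pi, 30000)
        rad = r * np.sqrt(rng.uniform(size=30000))
        x = (R + rad * np.cos(phi)) * np.cos(th) - R
        y = rad * np.sin(phi)
        z = -(R + rad * np.cos(phi)) * np.sin(th)
        pts = np.c_[x, y, z]
        ta = np.linspace(0, np.pi / 2, 30)
        knots = np.c_[R * np.cos(ta) - R, np.zeros_like(ta), -R * np.sin(ta)]
        path = og.fit_on_curve(knots)
        secs = og.cross_sections(path, pts, n_sections=15, n_angles=36,
                                 junction_x=[0, 1, 0])
        areas = np.array([s.area for s in secs if s.valid])
        assert np.all(np.abs(areas - np.pi * r**2) / (np.pi * r**2) < 0.07)

    def test_cylinder_volume_and_refinement_stability(self):
        pts = _tube(120000, radius=1.5)
        knots = np.outer(np.linspace(0, 26, 12), [0, 0, -1.0])
        path = og.fit_on_curve(knots)
        v1 = og.on_volume(
            og.cross_sections(path, pts, n_sections=25, junction_x=[1, 0, 0]), path
        )
        v2 = og.on_volume(
            og.cross_sections(path, pts, n_sections=50, junction_x=[1, 0, 0]), path
        )
        expected = np.pi * 1.5**2 * 26.0
        assert v1 == pytest.approx(expected, rel=0.05)
        assert abs(v2 - v1) / v1 < 0.01

    def test_sparse_slab_marked_invalid(self):
        pts = _tube(4000)
        pts = pts[pts[:, 2] > -20]  # truncate the posterior part
        knots = np.outer(np.linspace(0, 26, 12), [0, 0, -1.0])
        path = og.fit_on_curve(knots)
        secs = og.cross_sections(path, pts, n_sections=20, junction_x=[1, 0, 0])
        assert any(not s.valid for s in secs)
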