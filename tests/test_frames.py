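import itertools

import numpy as np
import pytest

from onstrain.frames import (
    Frame,
    build_head_frame,
    duction_angle,
    globe_center,
    minimal_enclosing_sphere,
    muscle_insertion,
    ocular_axis,
    torsion_angle,
)
from onstrain.registration import PlaneParams
from onstrain.transforms import RigidTransform


def brute_force_min_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """O(N^4) oracle: smallest circumsphere of any <=4-point support set
    that encloses all points."""
    from onstrain.frames import _circumsphere

    best = (None, np.inf)
    n = len(points)
    for k in (1, 2, 3, 4):
        for idx in itertools.combinations(range(n), k):
            c, r = _circumsphere(points[list(idx)])
            if r < 0:
                continue
            if np.all(np.linalg.norm(points - c, axis=1) <= r + 1e-9):
                if r < best[1]:
                    best = (c, r)
    return best


class TestMinimalSphere:
    def test_axis_extremes(self):
        r = 5.0
        pts = np.vstack([np.eye(3) * r, -np.eye(3) * r])
        c, rad = minimal_enclosing_sphere(pts)
        assert np.allclose(c, 0, atol=1e-9)
        assert rad == pytest.approx(r, abs=1e-9)

    def test_dense_sphere_samples(self, rng):
        center = np.array([3.0, -2.0, 7.0])
        p = rng.normal(size=(1000, 3))
        p = 12.0 * p / np.linalg.norm(p, axis=1, keepdims=True) + center
        c, rad = minimal_enclosing_sphere(p)
        assert np.allclose(c, center, atol=1e-6)
        assert rad == pytest.approx(12.0, abs=1e-6)

    def test_matches_bruteforce_on_random_sets(self, rng):
        for k in range(20):
            pts = rng.normal(size=(10, 3)) * 3
            c, r = minimal_enclosing_sphere(pts, seed=k)
            cb, rb = brute_force_min_sphere(pts)
            assert r == pytest.approx(rb, abs=1e-7)
            assert np.allclose(c, cb, atol=1e-6)

    def test_invariant_to_order_and_rigid_motion(self, rng):
        pts = rng.normal(size=(30, 3)) * 4
        c1, r1 = minimal_enclosing_sphere(pts, seed=0)
        c2, r2 = minimal_enclosing_sphere(pts[::-1], seed=5)
        assert np.allclose(c1, c2, atol=1e-7) and r1 == pytest.approx(r2, abs=1e-9)
        T = RigidTransform.from_axis_angle([1, 2, 3], 33.0, translation=[5, -1, 2])
        c3, r3 = minimal_enclosing_sphere(T.apply(pts), seed=0)
        assert np.allclose(c3, T.apply(c1), atol=1e-7)
        assert r3 == pytest.approx(r1, abs=1e-9)

    def test_globe_center_needs_points(self):
        with pytest.raises(ValueError):
            globe_center(np.zeros((3, 3)))


class TestHeadFrame:
    def test_direct_construction_matches_closed_form(self):
        plane = PlaneParams([1, 0, 0], 0.0)
        Z_expect = np.array([0.0, -np.sin(np.deg2rad(10)), np.cos(np.deg2rad(10))])
        fr = build_head_frame(plane, [0, 0, 0], [0, 0, 10], pitch_deg=10.0,
                              anterior_hint=[0, 0, 1])
        assert np.allclose(fr.Z, Z_expect, atol=1e-12)
        assert np.linalg.det(fr.axes) == pytest.approx(1.0, abs=1e-12)

    def test_lateral_hint_orients_x(self):
        plane = PlaneParams([-1, 0, 0], 0.0)
        fr = build_head_frame(plane, [0, 0, 0], [0, 0, 10],
                              lateral_hint=[1, 0, 0], anterior_hint=[0, 0, 1])
        assert fr.X @ [1, 0, 0] > 0.99

    def test_degenerate_recess_line_errors(self):
        plane = PlaneParams([1, 0, 0], 0.0)
        with pytest.raises(ValueError):
            build_head_frame(plane, [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            build_head_frame(plane, [0, 0, 0], [10, 0, 0])  # parallel to normal

    def test_frame_validation(self):
        with pytest.raises(ValueError):
            Frame(np.zeros(3), [1, 0, 0], [1, 0, 0], [0, 0, 1])


def _eye_cloud(rotation=None, n=6000, seed=0, bulge=1.5):
    """Sphere shell + corneal cap cloud, optionally rotated about origin."""
    rng = np.random.default_rng(seed)
    p = rng.normal(size=(n, 3))
    p = 12.0 * p / np.linalg.norm(p, axis=1, keepdims=True)
    ck = np.array([0, 0, 12.0 + bulge - 7.8])
    m = rng.normal(size=(n // 6, 3))
    m = 7.8 * m / np.linalg.norm(m, axis=1, keepdims=True) + ck
    cap = m[np.linalg.norm(m, axis=1) > 12.0]
    pts = np.vstack([p[np.linalg.norm(p - ck, axis=1) > 7.8], cap])
    if rotation is not None:
        pts = rotation.apply(pts)
    return pts


class TestDuction:
    def test_unrotated_eye_near_zero(self):
        head = Frame.canonical()
        assert abs(duction_angle(_eye_cloud(), head, center=np.zeros(3))) < 0.5

    @pytest.mark.parametrize("angle", [-28.0, 24.0, 40.0])
    def test_imposed_rotation_recovered(self, angle):
        head = Frame.canonical()
        R = RigidTransform.from_axis_angle([0, 1, 0], angle)
        got = duction_angle(_eye_cloud(R), head, center=np.zeros(3))
        assert got == pytest.approx(angle, abs=1.0)

    def test_translation_does_not_bias_angle(self):
        head = Frame.canonical()
        R = RigidTransform.from_axis_angle([0, 1, 0], 24.0, translation=[0.5, 0, 0])
        got = duction_angle(_eye_cloud(R) , head, center=np.array([0.5, 0, 0]))
        assert got == pytest.approx(24.0, abs=1.0)


class TestTorsion:
    def _markers(self, transform):
        lr = transform.apply(np.array([12.0, 0, 0]))
        mr = transform.apply(np.array([-12.0, 0, 0]))
        axis = transform.rotation @ np.array([0, 0, 1.0])
        return lr, mr, axis

    def test_pure_horizontal_rotation_gives_zero(self):
        T0 = RigidTransform.identity()
        T1 = RigidTransform.from_axis_angle([0, 1, 0], 28.0)
        lr0, mr0, a0 = self._markers(T0)
        lr1, mr1, a1 = self._markers(T1)
        assert abs(torsion_angle(lr0, mr0, lr1, mr1, a0, a1)) < 1e-9

    @pytest.mark.parametrize("tors,duction", [(5.0, 0.0), (-3.0, -28.0)])
    def test_imposed_torsion_recovered(self, tors, duction):
        T0 = RigidTransform.identity()
        T1 = RigidTransform.from_axis_angle([0, 1, 0], duction).compose(
            RigidTransform.from_axis_angle([0, 0, 1], tors)
        )
        lr0, mr0, a0 = self._markers(T0)
        lr1, mr1, a1 = self._markers(T1)
        got = torsion_angle(lr0, mr0, lr1, mr1, a0, a1)
        assert got == pytest.approx(tors, abs=0.5)

    def test_collinear_chord_errors(self):
        with pytest.raises(ValueError):
            torsion_angle([0, 0, 12], [0, 0, -12], [0, 0, 12], [0, 0, -12],
                          [0, 0, 1], [0, 0, 1])


def test_muscle_insertion_finds_band_end(rng):
    band = np.c_[np.linspace(12, 25, 800), rng.normal(0, 1.5, 800),
                 np.linspace(0, -20, 800)]
    marker = muscle_insertion(band, np.zeros(3), 12.0)
    # the end of the band nearest the globe is around (12, 0, 0)
    assert np.linalg.norm(marker - [12.3, 0, -0.5]) < 1.5
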