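import numpy as np
import pytest

from onstrain import ongeometry as og
from onstrain import strain as st
from onstrain.frames import Frame
from onstrain.transforms import RigidTransform


def _grid(n=12, spacing=0.6, seed=0):
    rng = np.random.default_rng(seed)
    g = np.arange(n) * spacing
    X, Y, Z = np.meshgrid(g[:3], g[:3], g, indexing="ij")
    pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
    return pts + rng.normal(0, 0.02 * spacing, pts.shape)


class TestDisplacementGradient:
    def test_affine_field_exact(self, rng):
        pts = rng.normal(size=(400, 3))
        A = np.array([[0.02, 0.01, 0.0], [0.0, -0.03, 0.005], [0.01, 0.0, 0.05]])
        u = pts @ A.T
        grads, rep = st.displacement_gradient(pts, u)
        ok = ~rep.flagged
        assert ok.sum() > 350
        assert np.abs(grads[ok] - A).max() < 1e-9

    def test_quadratic_field_first_order_convergence(self):
        errs = []
        for h in (0.6, 0.3):
            pts = _grid(spacing=h, seed=1)
            u = np.zeros_like(pts)
            u[:, 2] = pts[:, 0] ** 2
            grads, rep = st.displacement_gradient(pts, u)
            ok = ~rep.flagged
            err = np.abs(grads[ok, 2, 0] - 2 * pts[ok, 0])
            errs.append(np.median(err))
        ratio = errs[1] / errs[0]
        # halving h halves the error, within 20 percent
        assert 0.3 < ratio < 0.72

    def test_coplanar_neighbors_flagged_not_silent(self):
        pts = np.c_[np.random.default_rng(0).normal(size=(60, 2)), np.zeros(60)]
        u = np.zeros_like(pts)
        u[:, 2] = pts[:, 2]
        grads, rep = st.displacement_gradient(pts, u)
        assert rep.flagged.all()

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            st.displacement_gradient(np.zeros((4, 3)), np.zeros((4, 3)))


class TestGreenLagrange:
    def test_zero_gradient(self):
        assert np.allclose(st.green_lagrange(np.zeros((3, 3))), 0)

    def test_uniaxial_stretch_closed_form(self):
        g = np.diag([0.0, 0.0, 0.05])
        E = st.green_lagrange(g)
        assert E[2, 2] == pytest.approx(0.05 + 0.05**2 / 2, abs=1e-15)
        assert np.abs(E - np.diag([0, 0, E[2, 2]])).max() < 1e-15

    def test_rotation_gives_zero(self):
        R = RigidTransform.from_axis_angle([0, 1, 0], 20.0).rotation
        E = st.green_lagrange(R - np.eye(3))
        assert np.abs(E).max() < 1e-12

    def test_compat_mode_omits_half(self):
        g = np.diag([0.0, 0.0, 0.05])
        E = st.green_lagrange(g, compat_no_half=True)
        assert E[2, 2] == pytest.approx(2 * 0.05 + 0.05**2, abs=1e-15)

    def test_symmetry_batch(self, rng):
        g = rng.normal(0, 0.1, (50, 3, 3))
        E = st.green_lagrange(g)
        assert np.abs(E - np.transpose(E, (0, 2, 1))).max() < 1e-12


class TestTangentialStrain:
    def test_along_and_across(self):
        E = np.diag([0.0, 0.0, 0.05125])
        assert st.tangential_strain(E, np.array([0, 0, 1.0])) == pytest.approx(0.05125)
        assert st.tangential_strain(E, np.array([1.0, 0, 0])) == pytest.approx(0.0)

    def test_batch_with_per_sample_directions(self, rng):
        E = np.tile(np.diag([0.0, 0.0, 0.05]), (10, 1, 1))
        z = np.tile([0, 0, 1.0], (10, 1))
        out = st.tangential_strain(E, z)
        assert np.allclose(out, 0.05)


class TestRegionalSummary:
    def test_constant_field(self):
        s = np.linspace(0, 1, 500)
        u = np.zeros((500, 3))
        e = np.full(500, 0.05125)
        df = st.regional_summary(s, u, e)
        assert list(df.region) == ["G1", "G2", "G3", "G4", "G5"]
        assert np.allclose(df.mean_Ezz, 0.05125)
        assert np.allclose(df.se_Ezz, 0.0)

    def test_empty_region_reported_missing(self):
        s = np.concatenate([np.linspace(0, 0.39, 100), np.linspace(0.6, 1, 100)])
        u = np.zeros((200, 3))
        e = np.zeros(200)
        df = st.regional_summary(s, u, e)
        row = df[df.region == "G3"].iloc[0]
        assert row.n == 0 and np.isnan(row.mean_Ezz)


class TestSheathRatios:
    def test_nested_circles_closed_form(self):
        inner, outer = st.sheath_ratios(np.pi, 4 * np.pi, 9 * np.pi)
        assert inner == pytest.approx(2.0)
        assert outer == pytest.approx(3.0)

    def test_nesting_violation_errors(self):
        with pytest.raises(ValueError):
            st.sheath_ratios(4 * np.pi, 4 * np.pi, 9 * np.pi)


def _analytic_configuration(deform=None, n=40000, seed=0):
    """ONConfiguration of a straight tube cloud (optionally deformed)."""
    rng = np.random.default_rng(seed)
    z = rng.uniform(0, 26, n)
    th = rng.uniform(0, 2 * np.pi, n)
    r = 1.5 * np.sqrt(rng.uniform(size=n))
    pts = np.c_[r * np.cos(th), r * np.sin(th), -z]
    if deform is not None:
        pts = deform(pts)
    knots = np.outer(np.linspace(0, 26, 14), [0, 0, -1.0])
    if deform is not None:
        knots = deform(knots)
    path = og.fit_on_curve(knots)
    secs = og.cross_sections(path, pts, n_sections=20, n_angles=36,
                             junction_x=[1, 0, 0])
    return st.ONConfiguration(path, secs)


class TestMatching:
    def test_identity_match_has_zero_separation(self):
        cfg0 = _analytic_configuration()
        matched = st.match_points(cfg0, cfg0)
        u = st.displacement_field(matched)
        assert np.abs(u).max() < 1e-12

    def test_pure_translation_recovered(self):
        shift = np.array([1.0, 2.0, 3.0])
        cfg0 = _analytic_configuration()
        cfg1 = _analytic_configuration(deform=lambda p: p + shift)
        matched = st.match_points(cfg0, cfg1)
        u = st.displacement_field(matched)
        assert np.abs(u - shift).max() < 0.2

    def test_invalid_stations_dropped(self):
        cfg0 = _analytic_configuration()
        cfg1 = _analytic_configuration()
        cfg1.sections[7].valid = False
        matched = st.match_points(cfg0, cfg1)
        assert 7 in matched.dropped_stations
        assert 7 not in set(matched.station)

    def test_station_count_mismatch_errors(self):
        cfg0 = _analytic_configuration()
        cfg1 = _analytic_configuration()
        cfg1.sections.pop()
        with pytest.raises(ValueError):
            st.match_points(cfg0, cfg1)


def test_smooth_displacements_preserves_quadratic_profile():
    cfg0 = _analytic_configuration()
    matched = st.match_points(cfg0, cfg0)
    u = np.zeros((len(matched), 3))
    u[:, 2] = 0.1 * matched.s + 0.05 * matched.s**2
    out = st.smooth_displacements(matched, u, window=9)
    assert np.abs(out - u).max() < 1e-9
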