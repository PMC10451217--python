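"""Synthetic orbit scenes with analytic deformation ground truth.

The generator builds a parametric left orbit in a canonical head frame
(origin at the reference globe center; +X temporal/lateral, +Y superior,
+Z anterior; all mm):

* a rigid globe: scleral sphere plus a protruding corneal cap (the cap makes
  the ocular orientation observable from the surface cloud);
* an optic nerve: a tube of radius ``on_radius`` around a gently helical
  path (a constant-slope transverse offset that vanishes at both ends)
  running from the globe-ON junction to the orbital apex, surrounded by a
  CSF gap and a dural sheath annulus (the ONS); the constant slope makes
  normalized arc length coincide with normalized chord position, so the
  fixed-plane material correspondence the measurement relies on is exact;
* two horizontal rectus muscle bands (LR temporal, MR nasal) inserting on
  the globe equator and anchored near the apex;
* a conical orbital wall with its vertex at the apex.

Gaze states impose a rigid globe pose (duction about the vertical axis,
optional torsion about the line of sight, translation) together with one of
three nerve deformation modes whose displacement fields have closed-form
Green-Lagrange strain:

``rigid_only``
    the nerve swings rigidly about the apex to follow the junction; strain
    is identically zero.
``uniform_stretch``
    the sinuous nerve straightens onto the junction-apex chord and every
    material fiber along the path stretches by ``1 + m`` (the adduction
    regime): tangential strain ``((1+m)^2 - 1)/2`` on the centerline, with
    the exact off-axis correction from straightening the helix.
``cantilever_bend``
    the nerve swings rigidly about the apex, then its transverse helical
    slack grows quadratically toward the apex while every material point
    keeps its chordwise station (the abduction regime, where the slack
    nerve bends rather than stretches uniformly): displacement is largest
    at the globe (the swing), tangential strain is near zero at the globe
    and grows monotonically toward the apex, and tortuosity increases.

Scenes are sampled onto two anisotropic acquisition grids (quasicoronal:
fine in-plane, thick slices along the orbital axis; axial: fine in-plane
horizontally, thick slices vertically), each expressed in its own randomly
offset acquisition frame, emulating two MRI sessions to be registered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .pointcloud import ImageStack, Label, LabeledPointCloud, voxelize  # noqa: F401
from .registration import PlaneParams
from .transforms import RigidTransform, rotation_between

logger = logging.getLogger(__name__)

MODES = ("rigid_only", "uniform_stretch", "cantilever_bend")
TAGS = ("coronal_central", "axial_central", "coronal_gaze", "axial_gaze")


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and acquisition parameters of the synthetic orbit (mm, deg)."""

    globe_radius: float = 12.0
    on_length: float = 26.0  # arc length of the nerve path
    on_radius: float = 1.5
    sheath_inner_radius: float = 2.3
    sheath_outer_radius: float = 2.9
    sinuosity_amplitude: float = 0.9  # helical offset; tortuosity ~ 1.024
    muscle_width: float = 8.0
    muscle_thickness: float = 1.8
    orbit_cone_half_angle: float = 25.0
    wall_thickness: float = 0.9
    # azimuthal wall asymmetry: real orbits are not surfaces of revolution,
    # and a perfectly circular cone would leave inter-session registration
    # free to spin about the orbital axis. Even (cos 2phi) and third
    # (sin 3phi) harmonics break that symmetry without biasing the vertex of
    # a circular-cone fit.
    wall_ellipticity: float = 0.08
    wall_ripple: float = 0.04
    junction_offset_deg: float = 3.0  # nasal offset of the junction from the posterior pole
    chord_tilt_deg: float = 10.0  # nasal tilt of the junction-apex chord from -Z
    cornea_bulge: float = 1.5
    cornea_radius: float = 7.8
    coronal_inplane_spacing: float = 0.312
    coronal_slice_thickness: float = 2.0
    axial_inplane_spacing: float = 0.390
    axial_slice_thickness: float = 2.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (
            self.globe_radius, self.on_length, self.on_radius,
            self.sheath_inner_radius, self.sheath_outer_radius,
            self.muscle_width, self.muscle_thickness, self.wall_thickness,
            self.coronal_inplane_spacing, self.coronal_slice_thickness,
            self.axial_inplane_spacing, self.axial_slice_thickness,
            self.cornea_radius,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths must be positive")
        if not (self.sheath_outer_radius > self.sheath_inner_radius > self.on_radius):
            raise ValueError("need sheath_outer > sheath_inner > on_radius")
        if not (0 <= self.noise_sd < self.coronal_inplane_spacing):
            raise ValueError("noise_sd must lie in [0, coronal_inplane_spacing)")

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class GazeState:
    """Imposed gaze change relative to central gaze.

    ``duction_deg`` positive = abduction (temporal rotation about +Y).
    ``mode_magnitude`` is the stretch ratio minus one for uniform_stretch,
    or the extra transverse slack amplitude (mm) at the apex end for
    cantilever_bend (the tangential strain at the apex grows with it;
    ~0.7 mm over the default geometry gives the ~4-5% apex strain reported
    for large abduction).
    """

    duction_deg: float = 0.0
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    deformation_mode: str = "rigid_only"
    mode_magnitude: float = 0.0
    torsion_deg: float = 0.0

    def __post_init__(self) -> None:
        if abs(self.duction_deg) > 60:
            raise ValueError("duction limited to +/-60 degrees")
        if self.deformation_mode not in MODES:
            raise ValueError(f"unknown deformation mode {self.deformation_mode!r}")
        if self.deformation_mode == "rigid_only" and self.mode_magnitude != 0:
            raise ValueError("rigid_only implies mode_magnitude = 0")


# ---------------------------------------------------------------------------
# tube curves (arc length + rotation-minimizing frames)
# ---------------------------------------------------------------------------


class _TubeCurve:
    """Analytic 3D curve on xi in [0, 1] with arc-length tables, foot-point
    projection and rotation-minimizing frames (RMF).

    RMF (Bishop) transport keeps the cross-section frame twist-free, so tube
    coordinates (s, a, b) built on it give a diagonal map Jacobian and a
    closed-form Green-Lagrange tensor for tube-to-tube material maps:
    lambda = (|C1'|(1 - a kN1 - b kB1)) / (|C0'|(1 - a kN0 - b kB0)) along
    the reference tangent, identity transversely.
    """

    def __init__(self, point_fn, d1_fn, d2_fn, n_dense: int = 4001) -> None:
        from scipy.integrate import cumulative_simpson
        from scipy.interpolate import CubicSpline

        self._pf, self._d1f, self._d2f = point_fn, d1_fn, d2_fn
        xi = np.linspace(0.0, 1.0, n_dense)
        pts = point_fn(xi)
        speed = np.linalg.norm(d1_fn(xi), axis=1)
        arc = np.r_[0.0, cumulative_simpson(speed, x=xi)]
        self._xi = xi
        self._arc_spline = CubicSpline(xi, arc)
        self._xi_spline = CubicSpline(arc, xi)
        self.length = float(arc[-1])
        self._tree = cKDTree(pts)
        T = d1_fn(xi) / speed[:, None]
        N = self._double_reflection(pts, T)
        self._n_splines = [CubicSpline(xi, N[:, k]) for k in range(3)]
        self.start = pts[0]
        self.end = pts[-1]

    @staticmethod
    def _double_reflection(pts: np.ndarray, T: np.ndarray) -> np.ndarray:
        yhat = np.array([0.0, 1.0, 0.0])
        n0 = yhat - (yhat @ T[0]) * T[0]
        if np.linalg.norm(n0) < 1e-6:
            n0 = np.array([1.0, 0.0, 0.0]) - T[0][0] * T[0]
        n0 /= np.linalg.norm(n0)
        N = np.empty_like(pts)
        N[0] = n0
        for i in range(len(pts) - 1):
            v1 = pts[i + 1] - pts[i]
            c1 = v1 @ v1
            if c1 < 1e-30:
                N[i + 1] = N[i]
                continue
            nL = N[i] - (2.0 / c1) * (v1 @ N[i]) * v1
            tL = T[i] - (2.0 / c1) * (v1 @ T[i]) * v1
            v2 = T[i + 1] - tL
            c2 = v2 @ v2
            N[i + 1] = nL if c2 < 1e-30 else nL - (2.0 / c2) * (v2 @ nL) * v2
        return N

    # -- geometry ----------------------------------------------------------
    def point(self, xi) -> np.ndarray:
        scalar = np.ndim(xi) == 0
        p = self._pf(np.atleast_1d(np.asarray(xi, float)))
        return p[0] if scalar else p

    def d1(self, xi) -> np.ndarray:
        return self._d1f(np.atleast_1d(np.asarray(xi, float)))

    def speed(self, xi) -> np.ndarray:
        return np.linalg.norm(self.d1(xi), axis=1)

    def tangent(self, xi) -> np.ndarray:
        d = self.d1(xi)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    def arc(self, xi) -> np.ndarray:
        return self._arc_spline(np.clip(np.atleast_1d(xi), 0.0, 1.0))

    def xi_of_arc(self, s) -> np.ndarray:
        return np.clip(self._xi_spline(np.clip(np.atleast_1d(s), 0.0, self.length)),
                       0.0, 1.0)

    def frames(self, xi) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(T, N, B) orthonormal RMF triads at xi."""
        xi = np.atleast_1d(np.asarray(xi, float))
        T = self.tangent(xi)
        N = np.stack([s(xi) for s in self._n_splines], axis=1)
        N = N - np.einsum("ij,ij->i", N, T)[:, None] * T
        N /= np.linalg.norm(N, axis=1, keepdims=True)
        B = np.cross(T, N)
        return T, N, B

    def curvature_components(self, xi) -> tuple[np.ndarray, np.ndarray]:
        """(kN, kB): dT/ds projected onto the RMF normal axes."""
        xi = np.atleast_1d(np.asarray(xi, float))
        d1 = self.d1(xi)
        d2 = self._d2f(xi)
        sp2 = np.einsum("ij,ij->i", d1, d1)
        T, N, B = self.frames(xi)
        dTds = (d2 - np.einsum("ij,ij->i", d2, T)[:, None] * T) / sp2[:, None]
        return np.einsum("ij,ij->i", dTds, N), np.einsum("ij,ij->i", dTds, B)

    def max_curvature(self) -> float:
        kN, kB = self.curvature_components(np.linspace(0, 1, 801))
        return float(np.hypot(kN, kB).max())

    def foot(self, X: np.ndarray, n_newton: int = 4) -> np.ndarray:
        """Parameter xi of the nearest curve point for each row of X."""
        X = np.asarray(X, float).reshape(-1, 3)
        _, idx = self._tree.query(X)
        xi = self._xi[idx].copy()
        for _ in range(n_newton):
            C = self._pf(xi)
            d1 = self._d1f(xi)
            d2 = self._d2f(xi)
            r = X - C
            g = -2 * np.einsum("ij,ij->i", r, d1)
            h = 2 * (np.einsum("ij,ij->i", d1, d1) - np.einsum("ij,ij->i", r, d2))
            step = np.where(np.abs(h) > 1e-12,
                            -g / np.maximum(np.abs(h), 1e-12) * np.sign(h), 0.0)
            xi = np.clip(xi + np.clip(step, -0.05, 0.05), 0.0, 1.0)
        return xi

    def offsets(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Tube coordinates (xi, a, b) of world points."""
        X = np.asarray(X, float).reshape(-1, 3)
        xi = self.foot(X)
        _, N, B = self.frames(xi)
        r = X - self._pf(xi)
        return xi, np.einsum("ij,ij->i", r, N), np.einsum("ij,ij->i", r, B)

    def compose(self, xi, a, b) -> np.ndarray:
        """World points from tube coordinates."""
        xi = np.atleast_1d(np.asarray(xi, float))
        _, N, B = self.frames(xi)
        return self._pf(xi) + np.asarray(a, float)[:, None] * N \
            + np.asarray(b, float)[:, None] * B


def _helix_curve(j0: np.ndarray, c_hat: np.ndarray, D: float, amp: float,
                 n1: np.ndarray, n2: np.ndarray) -> _TubeCurve:
    """Constant-slope helical perturbation of the junction-apex chord.

    The transverse offset A[(cos 2 pi xi - 1) n1 + sin 2 pi xi n2] vanishes
    at both ends and has constant speed 2 pi A, so arc length accrues
    uniformly with the chord coordinate: normalized arc length and
    normalized chord position coincide, and the tortuosity
    sqrt(1 + (2 pi A / D)^2) is constant along the nerve.
    """
    two_pi = 2.0 * np.pi

    def pf(xi):
        ang = two_pi * xi
        return (j0[None, :] + np.outer(xi * D, c_hat)
                + amp * np.outer(np.cos(ang) - 1.0, n1)
                + amp * np.outer(np.sin(ang), n2))

    def d1f(xi):
        ang = two_pi * xi
        return (np.outer(np.full_like(xi, D), c_hat)
                + amp * two_pi * np.outer(-np.sin(ang), n1)
                + amp * two_pi * np.outer(np.cos(ang), n2))

    def d2f(xi):
        ang = two_pi * xi
        return (amp * two_pi**2 * np.outer(-np.cos(ang), n1)
                + amp * two_pi**2 * np.outer(-np.sin(ang), n2))

    return _TubeCurve(pf, d1f, d2f)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Analytic truth for one synthetic scene (all in the head frame)."""

    config: SceneConfig
    gaze: GazeState
    frame_transforms: dict[str, RigidTransform]  # tag -> (acq local -> head)
    globe_transform: RigidTransform  # full rigid globe pose map
    globe_translation: np.ndarray  # actual center displacement, mm
    displacement_map: Callable[[np.ndarray], np.ndarray]
    strain_map: Callable[[np.ndarray], np.ndarray]
    junction_point: np.ndarray  # reference junction
    junction_deformed: np.ndarray
    apex_point: np.ndarray
    path: _ReferencePath = field(repr=False, default=None)
    medial_plane: PlaneParams = None
    recess_points: tuple[np.ndarray, np.ndarray] = None
    head_frame_pitch_deg: float = 10.0

    @property
    def globe_rotation(self) -> RigidTransform:
        return self.globe_transform

    @property
    def on_arc_length(self) -> float:
        return self.path.length

    def true_tortuosity(self) -> float:
        return self.path.length / np.linalg.norm(self.apex_point - self.junction_point)

    def is_on_point(self, points: np.ndarray) -> np.ndarray:
        """True for points inside the reference ON tube."""
        X = np.asarray(points, float).reshape(-1, 3)
        xi = self.path.foot(X)
        d = np.linalg.norm(X - self.path.point(xi), axis=1)
        return (d <= self.config.on_radius + 1e-9) & (xi > 0) & (xi < 1)

    def tangential_strain_at(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth tangential strain (reference-tangent ZZ component)."""
        X = np.asarray(points, float).reshape(-1, 3)
        E = self.strain_map(X)
        xi = self.path.foot(X)
        T = self.path.tangent(xi)
        return np.einsum("ni,nij,nj->n", T, E, T)


def analytic_strain_at(
    gt: GroundTruth, points: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Green-Lagrange tensors at reference points.

    Returns (tensors, inside_mask); tensors for points outside the reference
    ON geometry are still evaluated from the analytic map but flagged False
    in the mask rather than silently returned.
    """
    X = np.asarray(points, float).reshape(-1, 3)
    return gt.strain_map(X), gt.is_on_point(X)


# ---------------------------------------------------------------------------
# deformation maps
# ---------------------------------------------------------------------------


class _Deformation:
    """Bundles phi, phi^-1, displacement and strain for one gaze state.

    All three modes share the tube-coordinate formalism: material points are
    (s, a, b) in the reference curve's RMF coordinates; the deformed
    position carries (a, b) unchanged into the deformed curve's RMF frame at
    the matched station. The Green-Lagrange tensor is then
    ``E = (lambda^2 - 1)/2 T0 T0^T`` with the closed-form fiber stretch
    ``lambda`` (see _TubeCurve).
    """

    def __init__(self, ref: _TubeCurve, cfg: SceneConfig, gaze: GazeState,
                 scene: "Scene"):
        self.ref = ref
        self.cfg = cfg
        self.gaze = gaze
        c = np.zeros(3)
        j0 = scene.j0
        apex = scene.apex
        yhat = np.array([0.0, 1.0, 0.0])
        self.apex = apex
        self.j0 = j0
        self.m = float(gaze.mode_magnitude)

        tor_axis = (c - j0) / np.linalg.norm(c - j0)  # anterior-pointing
        R_tor = RigidTransform.from_axis_angle(tor_axis, gaze.torsion_deg, center=c)
        R_duc = RigidTransform.from_axis_angle(yhat, gaze.duction_deg, center=c)
        R_g = R_duc.compose(R_tor)
        j_prov = R_g.apply(j0) + np.asarray(gaze.translation_mm, float)

        D0 = np.linalg.norm(j0 - apex)
        mode = gaze.deformation_mode

        if mode == "uniform_stretch":
            L1 = (1.0 + self.m) * ref.length
            radial = j_prov - apex
            j1 = apex + L1 * radial / np.linalg.norm(radial)
            self.T1 = (apex - j1) / L1
            n1 = np.cross(yhat, self.T1)
            if np.linalg.norm(n1) < 1e-9:
                n1 = np.array([1.0, 0.0, 0.0])
            self.N1 = n1 / np.linalg.norm(n1)
            self.B1 = np.cross(self.T1, self.N1)
            self.stretch = 1.0 + self.m
            self.j1 = j1
            j_final = j1
        else:
            # rigid swing about the apex toward the (horizontal) provisional
            # junction direction; tether length to the apex is preserved
            radial = j_prov - apex
            if mode == "cantilever_bend":
                radial = radial * np.array([1.0, 0.0, 1.0])
            j1 = apex + D0 * radial / np.linalg.norm(radial)
            R = rotation_between(j0 - apex, j1 - apex).rotation
            self.T_on = RigidTransform(R, apex - R @ apex)
            self.j1 = j1
            j_final = j1
            if mode == "cantilever_bend":
                # growing transverse helical slack: same chordwise stations,
                # amplitude A + m c^2, anchored at junction and apex
                e1 = R @ scene.n1
                e2 = R @ scene.n2
                d_hat = (apex - j1) / D0
                A = cfg.sinuosity_amplitude
                m = self.m
                two_pi = 2.0 * np.pi

                def B_of(c):
                    return A + m * c**2

                def pf(c):
                    ang = two_pi * c
                    B = B_of(c)
                    return (j1[None, :] + np.outer(c * D0, d_hat)
                            + np.outer(B * (np.cos(ang) - 1.0), e1)
                            + np.outer(B * np.sin(ang), e2))

                def d1f(c):
                    ang = two_pi * c
                    B = B_of(c)
                    Bp = 2.0 * m * c
                    return (np.outer(np.full_like(c, D0), d_hat)
                            + np.outer(Bp * (np.cos(ang) - 1.0) - B * two_pi * np.sin(ang), e1)
                            + np.outer(Bp * np.sin(ang) + B * two_pi * np.cos(ang), e2))

                def d2f(c):
                    ang = two_pi * c
                    B = B_of(c)
                    Bp = 2.0 * m * c
                    Bpp = 2.0 * m
                    c1 = Bpp * (np.cos(ang) - 1.0) - 2 * Bp * two_pi * np.sin(ang) \
                        - B * two_pi**2 * np.cos(ang)
                    c2 = Bpp * np.sin(ang) + 2 * Bp * two_pi * np.cos(ang) \
                        - B * two_pi**2 * np.sin(ang)
                    return np.outer(c1, e1) + np.outer(c2, e2)

                self.def_curve = _TubeCurve(pf, d1f, d2f)

        # globe follows its junction material point exactly
        t_g = j_final - R_g.apply(j0)
        self.globe_transform = RigidTransform(R_g.rotation, R_g.translation + t_g)
        self.globe_translation = self.globe_transform.apply(c) - c
        self.junction_deformed = j_final

    # -- maps --------------------------------------------------------------
    def phi(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float).reshape(-1, 3)
        mode = self.gaze.deformation_mode
        if mode == "rigid_only":
            return self.T_on.apply(X)
        xi, a, b = self.ref.offsets(X)
        if mode == "cantilever_bend":
            return self.def_curve.compose(xi, a, b)
        s1 = self.stretch * self.ref.arc(xi)
        return (self.j1[None, :] + np.outer(s1, self.T1)
                + a[:, None] * self.N1 + b[:, None] * self.B1)

    def phi_inv(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float).reshape(-1, 3)
        mode = self.gaze.deformation_mode
        if mode == "rigid_only":
            return self.T_on.inverse().apply(x)
        if mode == "cantilever_bend":
            xi, a, b = self.def_curve.offsets(x)
            return self.ref.compose(xi, a, b)
        w = x - self.j1
        s0 = np.clip((w @ self.T1) / self.stretch, 0.0, self.ref.length)
        xi = self.ref.xi_of_arc(s0)
        a = w @ self.N1
        b = w @ self.B1
        return self.ref.compose(xi, a, b)

    def displacement(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float).reshape(-1, 3)
        return self.phi(X) - X

    def strain(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float).reshape(-1, 3)
        mode = self.gaze.deformation_mode
        if mode == "rigid_only":
            return np.zeros((len(X), 3, 3))
        xi, a, b = self.ref.offsets(X)
        kN0, kB0 = self.ref.curvature_components(xi)
        denom = 1.0 - a * kN0 - b * kB0
        if mode == "uniform_stretch":
            lam = self.stretch / denom
        else:
            kN1, kB1 = self.def_curve.curvature_components(xi)
            lam = (self.def_curve.speed(xi) / self.ref.speed(xi)
                   * (1.0 - a * kN1 - b * kB1) / denom)
        T0 = self.ref.tangent(xi)
        TT = np.einsum("ni,nj->nij", T0, T0)
        return 0.5 * (lam**2 - 1.0)[:, None, None] * TT


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

MEDIAL_PLANE_X = -32.0  # head-frame x of the medial plane (globe center at 0)
_WALL_H_MIN = 3.0  # cone surface starts this far from the vertex (optic canal)
_RECESS_BASE = np.array([-16.0, 14.0, -4.0])  # nasal-superior orbit landmark


class Scene:
    """Derived geometry of one configured orbit (reference state)."""

    def __init__(self, config: SceneConfig):
        self.config = config
        c = config
        beta = np.deg2rad(c.junction_offset_deg)
        self.center = np.zeros(3)
        self.j0 = c.globe_radius * np.array([-np.sin(beta), 0.0, -np.cos(beta)])
        tilt = np.deg2rad(c.chord_tilt_deg)
        self.c_hat = np.array([-np.sin(tilt), 0.0, -np.cos(tilt)])
        two_pi_a = 2.0 * np.pi * c.sinuosity_amplitude
        if two_pi_a >= c.on_length:
            raise ValueError("sinuosity amplitude too large for the nerve length")
        D = float(np.sqrt(c.on_length**2 - two_pi_a**2))
        n1 = np.cross([0.0, 1.0, 0.0], self.c_hat)
        self.n1 = n1 / np.linalg.norm(n1)
        self.n2 = np.cross(self.c_hat, self.n1)
        self.chord = D
        self.path = _helix_curve(self.j0, self.c_hat, D, c.sinuosity_amplitude,
                                 self.n1, self.n2)
        if self.path.max_curvature() * c.on_radius >= 1.0:
            raise ValueError(
                "sinuosity amplitude too large: ON tube self-intersects "
                f"(bend radius {1.0 / self.path.max_curvature():.2f} mm <= "
                f"on_radius {c.on_radius} mm)"
            )
        self.apex = self.j0 + D * self.c_hat
        # orbital cone: vertex at the apex, opening toward the orbital rim
        axis = np.array([0.0, 0.0, 6.0]) - self.apex
        self.wall_axis = axis / np.linalg.norm(axis)
        self.wall_h_max = float((self.center - self.apex) @ self.wall_axis + 6.0)
        u = np.cross(self.wall_axis, [0.0, 1.0, 0.0])
        self.wall_u = u / np.linalg.norm(u)
        self.wall_v = np.cross(self.wall_axis, self.wall_u)
        # cornea cap center (on the reference line of sight, +Z)
        self.cornea_center = np.array(
            [0.0, 0.0, c.globe_radius + c.cornea_bulge - c.cornea_radius]
        )
        # muscle insertions on the equator at +/-90 deg from the corneal apex
        self.insertion_lr = np.array([c.globe_radius, 0.0, 0.0])
        self.insertion_mr = np.array([-c.globe_radius, 0.0, 0.0])
        # posterior anchors sit inside the cone (annulus-of-Zinn region): the
        # bands must not cross the wall shell, whose label they would punch
        # gaze-dependent holes into
        self.anchor_lr = self.apex + 8.0 * self.wall_axis + np.array([1.8, 0.0, 0.0])
        self.anchor_mr = self.apex + 8.0 * self.wall_axis + np.array([-1.8, 0.0, 0.0])

    def _wall_radius(self, h, phi):
        """Wall surface distance from the axis at depth h, azimuth phi."""
        cfg = self.config
        base = h * np.tan(np.deg2rad(cfg.orbit_cone_half_angle))
        return base * (1.0 + cfg.wall_ellipticity * np.cos(2 * phi)
                       + cfg.wall_ripple * np.sin(3 * phi))

    # -- membership --------------------------------------------------------
    def _band_mask(self, P, p, q, width, thick):
        s = q - p
        L = np.linalg.norm(s)
        s_hat = s / L
        yhat = np.array([0.0, 1.0, 0.0])
        w_dir = yhat - (yhat @ s_hat) * s_hat
        w_dir /= np.linalg.norm(w_dir)
        n_dir = np.cross(s_hat, w_dir)
        w = P - p
        t = w @ s_hat
        off = w - np.outer(t, s_hat)
        return (
            (t >= 0) & (t <= L)
            & (np.abs(off @ w_dir) <= width / 2)
            & (np.abs(off @ n_dir) <= thick / 2)
        )

    def _tube_dist(self, X):
        xi = self.path.foot(X)
        d = np.linalg.norm(X - self.path.point(xi), axis=1)
        return d, xi

    def labels_at(self, P: np.ndarray, deform: "_Deformation | None") -> np.ndarray:
        """Label of each head-frame point, for the reference state
        (``deform=None``) or a deformed gaze state."""
        P = np.asarray(P, float).reshape(-1, 3)
        cfg = self.config
        out = np.zeros(len(P), dtype=np.int16)

        # orbital wall (rigid across gazes)
        w = P - self.apex
        h = w @ self.wall_axis
        perp = w - np.outer(h, self.wall_axis)
        rho = np.linalg.norm(perp, axis=1)
        phi = np.arctan2(perp @ self.wall_v, perp @ self.wall_u)
        surf = (rho - self._wall_radius(h, phi)) * np.cos(
            np.deg2rad(cfg.orbit_cone_half_angle)
        )
        out[(h >= _WALL_H_MIN) & (h <= self.wall_h_max)
            & (np.abs(surf) <= cfg.wall_thickness / 2)] = Label.ORBITAL_WALL

        # muscles: insertion follows the globe, anchor fixed near the apex
        Tg = deform.globe_transform if deform is not None else RigidTransform.identity()
        for lab, ins, anc in (
            (Label.MR, self.insertion_mr, self.anchor_mr),
            (Label.LR, self.insertion_lr, self.anchor_lr),
        ):
            out[self._band_mask(P, Tg.apply(ins), anc,
                                cfg.muscle_width, cfg.muscle_thickness)] = lab

        # globe: scleral sphere + corneal cap, rigid pose
        x = Tg.inverse().apply(P)
        glb = (np.linalg.norm(x, axis=1) <= cfg.globe_radius) | (
            np.linalg.norm(x - self.cornea_center, axis=1) <= cfg.cornea_radius
        )
        out[glb] = Label.GLOBE

        # nerve + sheath: pull back through the deformation map; prefilter by
        # distance to the junction-apex chord to keep the foot search cheap
        j1 = deform.junction_deformed if deform is not None else self.j0
        seg = self.apex - j1
        Lseg = np.linalg.norm(seg)
        s_hat = seg / Lseg
        t = np.clip((P - j1) @ s_hat, 0.0, Lseg)
        bend_extra = (deform.m if deform is not None and
                      deform.gaze.deformation_mode == "cantilever_bend" else 0.0)
        near = (
            np.linalg.norm(P - j1 - np.outer(t, s_hat), axis=1)
            <= cfg.sheath_outer_radius
            + 2.0 * (cfg.sinuosity_amplitude + bend_extra) + 2.0
        )
        if near.any():
            Xref = deform.phi_inv(P[near]) if deform is not None else P[near]
            d, xi = self._tube_dist(Xref)
            # the nerve label never extends inside the globe itself
            interior = (xi > 1e-9) & (xi < 1 - 1e-9) & ~glb[near]
            sub = np.zeros(near.sum(), dtype=np.int16)
            sub[interior & (d >= cfg.sheath_inner_radius)
                & (d <= cfg.sheath_outer_radius)] = Label.ONS
            sub[interior & (d <= cfg.on_radius)] = Label.ON
            put = sub != 0
            idx = np.flatnonzero(near)[put]
            out[idx] = sub[put]
        return out

    # -- bookkeeping -------------------------------------------------------
    def deformation(self, gaze: GazeState) -> _Deformation:
        return _Deformation(self.path, self.config, gaze, self)

    def landmarks(self, deform: "_Deformation | None") -> np.ndarray:
        """Coarse support points for bounding boxes."""
        r = self.config.sheath_outer_radius + 1.5
        xi = np.linspace(0, 1, 40)
        pts = [self.path.point(xi)]
        if deform is not None:
            pts.append(deform.phi(pts[0]))
        gr = self.config.globe_radius + self.config.cornea_bulge + 1.0
        corners = np.array(
            [[sx, sy, sz] for sx in (-gr, gr) for sy in (-gr, gr) for sz in (-gr, gr)]
        )
        Tg = deform.globe_transform if deform is not None else RigidTransform.identity()
        pts.append(Tg.apply(corners))
        # wall rim circle
        ang = np.linspace(0, 2 * np.pi, 24)
        a_hat = self.wall_axis
        u = np.cross(a_hat, [0, 1.0, 0])
        u /= np.linalg.norm(u)
        v = np.cross(a_hat, u)
        rim_r = self.wall_h_max * np.tan(np.deg2rad(self.config.orbit_cone_half_angle))
        rim = (self.apex + self.wall_h_max * a_hat
               + rim_r * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))
        pts.append(rim)
        pts.append(np.vstack([self.anchor_lr, self.anchor_mr,
                              self.insertion_lr, self.insertion_mr]))
        tube = np.vstack(pts)
        pad = np.array([[r, 0, 0], [-r, 0, 0], [0, r, 0], [0, -r, 0], [0, 0, r], [0, 0, -r]])
        return (tube[:, None, :] + pad[None, :, :]).reshape(-1, 3)

    def medial_plane(self) -> PlaneParams:
        return PlaneParams(np.array([1.0, 0.0, 0.0]), MEDIAL_PLANE_X)

    def recess_points(self, pitch_deg: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
        """Two anterior-ethmoid-recess landmarks whose connecting line,
        pitched by ``pitch_deg`` about +X, reproduces the head Z axis."""
        v = RigidTransform.from_axis_angle([1.0, 0, 0], -pitch_deg).apply(
            np.array([0.0, 0.0, 1.0])
        )
        return _RECESS_BASE.copy(), _RECESS_BASE + 10.0 * v


# ---------------------------------------------------------------------------
# acquisition sampling
# ---------------------------------------------------------------------------


def _acquisition_frames(config: SceneConfig, scene: Scene) -> dict[str, RigidTransform]:
    """Random rigid acquisition frames (local -> head), seeded by the config."""
    yhat = np.array([0.0, 1.0, 0.0])
    anterior = -scene.c_hat
    xc = np.cross(yhat, anterior)
    xc /= np.linalg.norm(xc)
    base_cor = np.column_stack([xc, np.cross(anterior, xc), anterior])
    base_ax = np.column_stack([[1.0, 0, 0], [0, 0, -1.0], yhat])
    out = {}
    for i, tag in enumerate(TAGS):
        rng = np.random.default_rng([config.seed % (2**31), 101 + i])
        coronal = tag.startswith("coronal")
        max_rot, max_tr = (3.0, 2.0) if coronal else (10.0, 5.0)
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ang = rng.uniform(0.2, max_rot)
        off = RigidTransform.from_axis_angle(axis, ang)
        t = rng.uniform(-1, 1, 3)
        t *= rng.uniform(0.2, max_tr) / np.linalg.norm(t)
        base = base_cor if coronal else base_ax
        out[tag] = RigidTransform(off.rotation @ base, t)
    return out


def _grid_centers(
    T: RigidTransform,
    landmarks_head: np.ndarray,
    spacing: np.ndarray,
    clip_hi_z: float | None = None,
    margin: float = 1.5,
) -> tuple[np.ndarray, np.ndarray, tuple[int, int, int]]:
    """Local-frame voxel centers covering the landmarks: (centers, origin, shape)."""
    local = T.inverse().apply(landmarks_head)
    lo = local.min(axis=0) - margin
    hi = local.max(axis=0) + margin
    if clip_hi_z is not None:
        hi[2] = min(hi[2], clip_hi_z)
    shape = tuple(np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 2))
    ax = [lo[k] + spacing[k] * np.arange(shape[k]) for k in range(3)]
    centers = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    return centers, lo, shape


def _truncated_normal(rng, sd: float, shape) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    return np.clip(rng.normal(0.0, sd, shape), -3 * sd, 3 * sd)


def _sample_tag(
    scene: Scene,
    tag: str,
    T: RigidTransform,
    deform: _Deformation | None,
    as_stack: bool,
    rng: np.random.Generator,
):
    cfg = scene.config
    coronal = tag.startswith("coronal")
    spacing = np.array(
        [cfg.coronal_inplane_spacing] * 2 + [cfg.coronal_slice_thickness]
        if coronal
        else [cfg.axial_inplane_spacing] * 2 + [cfg.axial_slice_thickness]
    )
    clip = None
    if coronal:
        # quasicoronal stacks do not span the anterior globe (or the cornea)
        Tg = deform.globe_transform if deform is not None else RigidTransform.identity()
        c_local = T.inverse().apply(Tg.apply(scene.center))
        clip = float(c_local[2] + 7.0)
    centers, origin, shape = _grid_centers(T, scene.landmarks(deform), spacing, clip)

    if as_stack:
        sample_pts = centers + _truncated_normal(rng, cfg.noise_sd, centers.shape)
        labels = scene.labels_at(T.apply(sample_pts), deform)
        vol = labels.reshape(shape)
        return ImageStack(vol, spacing, origin, tag)

    labels = scene.labels_at(T.apply(centers), deform)
    keep = labels != 0
    pts = centers[keep] + _truncated_normal(rng, cfg.noise_sd, (int(keep.sum()), 3))
    return LabeledPointCloud(pts, labels[keep], tag)


def _build(config: SceneConfig, gaze: GazeState, as_stacks: bool):
    scene = Scene(config)
    deform = scene.deformation(gaze)
    frames = _acquisition_frames(config, scene)
    out = {}
    for i, tag in enumerate(TAGS):
        rng = np.random.default_rng([config.seed % (2**31), 211 + i])
        state = deform if tag.endswith("_gaze") else None
        out[tag] = _sample_tag(scene, tag, frames[tag], state, as_stacks, rng)
    gt = GroundTruth(
        config=config,
        gaze=gaze,
        frame_transforms=frames,
        globe_transform=deform.globe_transform,
        globe_translation=deform.globe_translation,
        displacement_map=deform.displacement,
        strain_map=deform.strain,
        junction_point=scene.j0.copy(),
        junction_deformed=deform.junction_deformed.copy(),
        apex_point=scene.apex.copy(),
        path=scene.path,
        medial_plane=scene.medial_plane(),
        recess_points=scene.recess_points(),
    )
    return out, gt


def generate_scene(
    config: SceneConfig, gaze: GazeState
) -> tuple[dict[str, LabeledPointCloud], GroundTruth]:
    """Labeled point clouds for the four acquisition tags plus ground truth.

    Each cloud is sampled on its acquisition grid (voxel centers of the
    structures present) in its own acquisition frame, then jittered by
    truncated Gaussian noise of ``config.noise_sd``. Regeneration with the
    same config and gaze is bit-identical.
    """
    return _build(config, gaze, as_stacks=False)


def generate_stacks(
    config: SceneConfig, gaze: GazeState
) -> tuple[dict[str, ImageStack], GroundTruth]:
    """Label image stacks for the four acquisition tags plus ground truth.

    Noise enters as truncated Gaussian jitter of the per-voxel sampling
    position (segmentation boundary jitter)."""
    return _build(config, gaze, as_stacks=True)


def sample_wall_points(
    config: SceneConfig, n: int = 4000, seed: int = 0, noise_sd: float | None = None
) -> np.ndarray:
    """Random head-frame points on the orbital wall cone shell."""
    scene = Scene(config)
    rng = np.random.default_rng(seed)
    h = _WALL_H_MIN + (scene.wall_h_max - _WALL_H_MIN) * np.sqrt(rng.uniform(size=n))
    ang = rng.uniform(0, 2 * np.pi, n)
    u, v = scene.wall_u, scene.wall_v
    r = scene._wall_radius(h, ang)
    pts = (scene.apex + np.outer(h, scene.wall_axis)
           + r[:, None] * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)))
    sd = config.noise_sd if noise_sd is None else noise_sd
    return pts + _truncated_normal(rng, sd, pts.shape)


def mirrored_wall_pair(
    config: SceneConfig, n: int = 4000, seed: int = 0, noise_sd: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Left and right orbital-wall clouds, mirror images about the medial
    plane, with independent noise."""
    scene = Scene(config)
    left = sample_wall_points(config, n, seed, noise_sd)
    plane = scene.medial_plane()
    right_clean = plane.reflect(sample_wall_points(config, n, seed + 1, 0.0))
    rng = np.random.default_rng(seed + 2)
    sd = config.noise_sd if noise_sd is None else noise_sd
    return left, right_clean + _truncated_normal(rng, sd, right_clean.shape)
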