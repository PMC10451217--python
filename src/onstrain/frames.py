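"""Head and globe coordinate systems, globe center and kinematics.

The head frame is anatomical: X is the medial-plane normal pointing from the
nose toward the orbit under analysis (so "nasal" is -X), Z points posterior
to anterior along the orbit, pitched 10 degrees from the anterior-ethmoid
recess line within the medial plane, and Y = Z x X points superiorly,
completing a right-handed triad.

The globe center is the center of the exact minimal enclosing sphere of the
globe cloud; ocular orientation is the line from the corneal apex to its
antipode, and torsion is read from the lateral/medial rectus insertions
after factoring out the duction rotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .transforms import RigidTransform, rotation_between

logger = logging.getLogger(__name__)


@dataclass
class Frame:
    """Orthonormal right-handed coordinate frame (origin + axes X, Y, Z)."""

    origin: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        for name in ("X", "Y", "Z"):
            v = np.asarray(getattr(self, name), float).reshape(3)
            n = np.linalg.norm(v)
            if abs(n - 1.0) > 1e-6:
                raise ValueError(f"frame axis {name} is not unit length")
            setattr(self, name, v / n)
        M = self.axes
        if not np.allclose(M.T @ M, np.eye(3), atol=1e-8):
            raise ValueError("frame axes are not orthonormal")
        if np.linalg.det(M) < 0:
            raise ValueError("frame is left-handed")

    @property
    def axes(self) -> np.ndarray:
        """3x3 matrix with columns X, Y, Z."""
        return np.column_stack([self.X, self.Y, self.Z])

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """World mm -> frame components."""
        p = np.asarray(points, float)
        return (p - self.origin) @ self.axes

    def from_local(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.axes.T + self.origin

    @classmethod
    def canonical(cls) -> "Frame":
        return cls(np.zeros(3), np.eye(3)[0], np.eye(3)[1], np.eye(3)[2])


@dataclass
class GlobeKinematics:
    """Per-gaze globe pose summary relative to the reference state."""

    center: np.ndarray
    duction_deg: float
    torsion_deg: float
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def translation_magnitude(self) -> float:
        return float(np.linalg.norm(self.translation))


# ---------------------------------------------------------------------------
# head frame
# ---------------------------------------------------------------------------


def build_head_frame(
    plane,
    recess_a: np.ndarray,
    recess_b: np.ndarray,
    pitch_deg: float = 10.0,
    origin: np.ndarray | None = None,
    lateral_hint: np.ndarray | None = None,
    anterior_hint: np.ndarray | None = None,
) -> Frame:
    """Head frame from the medial plane and the anterior-ethmoid recess line.

    X is the medial-plane normal (oriented along ``lateral_hint`` if given,
    i.e. toward the orbit under analysis). The recess line is projected into
    the medial plane and pitched by ``pitch_deg`` about X (positive pitches
    the anterior end inferiorly; the magnitude is anatomical convention, the
    sign a package convention). Z is the result, oriented
    posterior-to-anterior along ``anterior_hint``; Y = Z x X.
    """
    a = np.asarray(recess_a, float).reshape(3)
    b = np.asarray(recess_b, float).reshape(3)
    v = b - a
    if np.linalg.norm(v) < 1e-12:
        raise ValueError("recess points coincide")
    X = np.asarray(plane.normal, float).copy()
    if lateral_hint is not None and np.dot(X, np.asarray(lateral_hint, float)) < 0:
        X = -X
    v_m = v - np.dot(v, X) * X
    n = np.linalg.norm(v_m)
    if n < 1e-9 * np.linalg.norm(v):
        raise ValueError("recess line is parallel to the medial-plane normal")
    v_m /= n
    Z = RigidTransform.from_axis_angle(X, pitch_deg).apply(v_m)
    if anterior_hint is not None and np.dot(Z, np.asarray(anterior_hint, float)) < 0:
        Z = -Z
    Y = np.cross(Z, X)
    if origin is None:
        origin = 0.5 * (a + b)
    return Frame(origin, X, Y, Z)


# ---------------------------------------------------------------------------
# minimal enclosing sphere (Welzl-style incremental)
# ---------------------------------------------------------------------------


def _circumsphere(boundary: np.ndarray) -> tuple[np.ndarray, float]:
    """Smallest sphere with all ``boundary`` points on its surface."""
    P = np.asarray(boundary, float)
    k = len(P)
    if k == 0:
        return np.zeros(3), -1.0
    if k == 1:
        return P[0].copy(), 0.0
    # center satisfies 2 (p_i - p0) . (c - p0) = |p_i - p0|^2; lstsq gives the
    # minimal-norm (in-affine-hull) center for degenerate boundary sets
    p0 = P[0]
    A = 2.0 * (P[1:] - p0)
    rhs = np.einsum("ij,ij->i", P[1:] - p0, P[1:] - p0)
    x, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    c = p0 + x
    r = float(np.linalg.norm(P[0] - c))
    return c, r


def _sphere_contains(c: np.ndarray, r: float, p: np.ndarray, eps: float) -> bool:
    return np.linalg.norm(p - c) <= r * (1 + eps) + eps


def minimal_enclosing_sphere(
    points: np.ndarray, seed: int = 0, eps: float = 1e-10
) -> tuple[np.ndarray, float]:
    """Exact minimal enclosing sphere of a 3D point set.

    Incremental Welzl-style construction over shuffled points (unique
    optimum, so the result is order-invariant up to floating-point noise).
    """
    P = np.unique(np.asarray(points, float).reshape(-1, 3), axis=0)
    rng = np.random.default_rng(seed)
    P = P[rng.permutation(len(P))]

    def ball(pts: np.ndarray, boundary: list[np.ndarray]) -> tuple[np.ndarray, float]:
        c, r = _circumsphere(np.array(boundary)) if boundary else (np.zeros(3), -1.0)
        if len(boundary) == 4:
            return c, r
        for i in range(len(pts)):
            p = pts[i]
            if r < 0 or not _sphere_contains(c, r, p, eps):
                c, r = ball(pts[:i], boundary + [p])
        return c, r

    return ball(P, [])


def globe_center(points: np.ndarray, seed: int = 0) -> tuple[np.ndarray, float]:
    """Center and radius of the minimal bounding sphere of the globe cloud.

    Runs on convex-hull vertices for speed. Degenerate (coplanar) clouds fall
    back to the minimal sphere of the raw points (logged), which for coplanar
    input is the minimal enclosing circle lifted to 3D.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 4:
        raise ValueError("globe_center needs at least 4 points")
    try:
        hull = ConvexHull(pts)
        pts = pts[hull.vertices]
    except QhullError:
        logger.warning("degenerate (coplanar) globe cloud; minimal circle fallback")
    return minimal_enclosing_sphere(pts, seed=seed)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------


def globe_translation(
    center_initial: np.ndarray,
    center_deformed: np.ndarray,
    head: Frame,
) -> tuple[np.ndarray, float]:
    """Head-frame components and magnitude of the globe-center displacement."""
    d = np.asarray(center_deformed, float) - np.asarray(center_initial, float)
    comps = d @ head.axes
    return comps, float(np.linalg.norm(comps))


def _extreme_patch_centroid(
    points: np.ndarray, score: np.ndarray, tol: float
) -> np.ndarray:
    """Weighted centroid of the patch around a smooth surface extremum.

    Points are weighted by how far their score exceeds ``max - tol``; the
    soft window makes the estimate geometry-dominated (hundreds of points
    of a symmetric cap) rather than selected by the noise tail.
    """
    w = np.clip(score - (score.max() - tol), 0.0, None)
    return (points * w[:, None]).sum(axis=0) / w.sum()


def ocular_axis(
    globe_points: np.ndarray,
    tol: float = 0.6,
    center: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(apex, antipode, unit axis) of the eye from its surface cloud.

    The corneal apex is the radial extreme from the globe center (the cornea
    protrudes beyond the scleral sphere); the antipode is the surface point
    farthest from the apex. Near-ties within ``tol`` mm are averaged; ``tol`` should exceed the
    point noise by a few SD so the patch is selected by geometry, not by
    the noise tail.
    """
    pts = np.asarray(globe_points, float).reshape(-1, 3)
    if center is None:
        center, _ = globe_center(pts)
    radial = np.linalg.norm(pts - center, axis=1)
    apex = _extreme_patch_centroid(pts, radial, tol)
    from_apex = np.linalg.norm(pts - apex, axis=1)
    antipode = _extreme_patch_centroid(pts, from_apex, tol)
    axis = apex - antipode
    n = np.linalg.norm(axis)
    if n < 1e-9:
        raise ValueError("degenerate ocular axis")
    return apex, antipode, axis / n


def duction_angle(
    globe_points: np.ndarray,
    head: Frame,
    tol: float = 0.6,
    projection: str = "horizontal",
    center: np.ndarray | None = None,
) -> float:
    """Signed duction angle in degrees; positive = abduction (+X swing).

    By default the ocular axis is projected into the horizontal (XZ) plane of
    the head frame; ``projection="3d"`` returns the full 3D angle from the
    head Z-axis (unsigned in elevation, signed by the horizontal component).
    Pass the globe ``center`` measured from cornea-free (quasicoronal) data:
    a center estimated from a cloud that includes the protruding cornea is
    biased anteriorly, which can flip the radial-extreme apex detection.
    """
    _, _, axis = ocular_axis(globe_points, tol=tol, center=center)
    ax = axis @ head.axes  # components (X, Y, Z)
    if projection == "horizontal":
        return float(np.degrees(np.arctan2(ax[0], ax[2])))
    if projection == "3d":
        ang = np.degrees(np.arccos(np.clip(ax[2], -1, 1)))
        return float(np.sign(ax[0]) * ang) if ax[0] != 0 else float(ang)
    raise ValueError(f"unknown projection {projection!r}")


def muscle_insertion(
    muscle_points: np.ndarray,
    globe_center_: np.ndarray,
    globe_radius: float,
    shell_tol: float = 1.0,
    end_tol: float = 1.5,
) -> np.ndarray:
    """Insertion marker: the anterior end of the muscle band.

    The band's termination on the globe is a material feature that moves
    rigidly with the eye; a soft extreme-patch centroid along the band's
    principal axis locates it stably even as the imaged coverage of the
    band changes with gaze. ``shell_tol`` only validates that the band
    actually reaches the globe.
    """
    pts = np.asarray(muscle_points, float).reshape(-1, 3)
    c_g = np.asarray(globe_center_, float)
    dist = np.linalg.norm(pts - c_g, axis=1)
    if not (dist <= globe_radius + shell_tol).any():
        raise ValueError("no muscle points near the globe surface")
    p0 = pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts - p0, full_matrices=False)
    axis = Vt[0]
    if axis @ (c_g - p0) < 0:
        axis = -axis  # point toward the globe
    score = (pts - p0) @ axis
    return _extreme_patch_centroid(pts, score, end_tol)


def duction_change_from_insertions(
    lr_initial: np.ndarray,
    mr_initial: np.ndarray,
    lr_deformed: np.ndarray,
    mr_deformed: np.ndarray,
    head: Frame,
) -> float:
    """Duction change (deg) from the horizontal rotation of the LR-MR chord.

    The insertion chord spans the globe equator (~24 mm), so patch-centroid
    noise of ~0.1 mm translates to ~0.25 deg — considerably steadier than
    the corneal-apex axis on partially covered clouds. Positive = abduction.
    """
    def horiz_angle(chord: np.ndarray) -> float:
        c = np.asarray(chord, float) @ head.axes
        return float(np.degrees(np.arctan2(-c[2], c[0])))

    return horiz_angle(np.asarray(lr_deformed) - np.asarray(mr_deformed)) - \
        horiz_angle(np.asarray(lr_initial) - np.asarray(mr_initial))


def torsion_change_about_head(
    lr_initial: np.ndarray,
    mr_initial: np.ndarray,
    lr_deformed: np.ndarray,
    mr_deformed: np.ndarray,
    head: Frame,
) -> float:
    """Torsion change (deg) from the insertion chord's elevation angle.

    For horizontal duction (rotation about head Y) the chord's Y component
    is invariant, so the change of its elevation angle isolates torsion
    without needing the duction estimate at all. Positive = intorsion of a
    left eye viewed along +Z (right-handed about the line of sight).
    """
    def elev(chord: np.ndarray) -> float:
        c = np.asarray(chord, float) @ head.axes
        horiz = np.hypot(c[0], c[2])
        return float(np.degrees(np.arctan2(c[1], horiz)))

    return elev(np.asarray(lr_deformed) - np.asarray(mr_deformed)) - \
        elev(np.asarray(lr_initial) - np.asarray(mr_initial))


def torsion_angle(
    lr_initial: np.ndarray,
    mr_initial: np.ndarray,
    lr_deformed: np.ndarray,
    mr_deformed: np.ndarray,
    axis_initial: np.ndarray,
    axis_deformed: np.ndarray,
) -> float:
    """Torsion change (deg) from the LR-MR insertion chord, duction removed.

    The reference chord is carried through the minimal rotation mapping the
    initial ocular axis to the deformed one; the signed residual rotation of
    the deformed chord about the deformed axis is the torsion change
    (positive = right-handed about the line of sight).
    """
    a0 = np.asarray(axis_initial, float)
    a1 = np.asarray(axis_deformed, float)
    a0 = a0 / np.linalg.norm(a0)
    a1 = a1 / np.linalg.norm(a1)
    chord0 = np.asarray(lr_initial, float) - np.asarray(mr_initial, float)
    chord1 = np.asarray(lr_deformed, float) - np.asarray(mr_deformed, float)
    chord0 = rotation_between(a0, a1).apply(chord0)

    def _proj(v: np.ndarray) -> np.ndarray:
        w = v - np.dot(v, a1) * a1
        n = np.linalg.norm(w)
        if n < 1e-6 * np.linalg.norm(v):
            raise ValueError("insertion chord is collinear with the ocular axis")
        return w / n

    u0, u1 = _proj(chord0), _proj(chord1)
    s = float(np.dot(np.cross(u0, u1), a1))
    c = float(np.dot(u0, u1))
    return float(np.degrees(np.arctan2(s, c)))
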