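"""Optic-nerve centerline extraction and tube parameterization.

The ON is reduced to an ordered set of per-bin centroids, anchored
anteriorly at the globe-ON junction (ray/convex-hull intersection) and
posteriorly at the pseudo orbital apex (intersection of the straightened
large-adduction nerve line with a cone fitted to the posterior orbital
wall). Junction, centroids and apex become knot points for a least-squares
cubic B-spline curve, which is arc-length reparameterized; cross-sections
normal to the curve give polar boundary samples, areas and the nerve volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline, make_lsq_spline
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .frames import Frame

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# centroids, junction, apex
# ---------------------------------------------------------------------------


def fit_line(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares line fit: (centroid, unit direction, RMS distance)."""
    P = np.asarray(points, float).reshape(-1, 3)
    c = P.mean(axis=0)
    Q = P - c
    _, s, Vt = np.linalg.svd(Q, full_matrices=False)
    d = Vt[0]
    resid = Q - np.outer(Q @ d, d)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return c, d, rms


def on_centroids(
    on_points: np.ndarray,
    long_axis: np.ndarray | None = None,
    bin_width: float = 0.33,
    min_points: int = 5,
    anterior_point: np.ndarray | None = None,
) -> np.ndarray:
    """Per-bin centroids of the ON cloud along its long axis, ordered
    anterior to posterior.

    ``long_axis`` defaults to the principal axis of the cloud. Bins with
    fewer than ``min_points`` points are merged into the neighboring bin
    (logged). ``anterior_point`` (e.g. the globe center) orients the
    ordering; without it the +axis end is taken as anterior.
    """
    P = np.asarray(on_points, float).reshape(-1, 3)
    if len(P) == 0:
        raise ValueError("empty ON cloud")
    if long_axis is None:
        _, long_axis, _ = fit_line(P)
    axis = np.asarray(long_axis, float)
    axis = axis / np.linalg.norm(axis)
    t = P @ axis
    lo, hi = t.min(), t.max()
    n_bins = int(np.ceil((hi - lo) / bin_width))
    if n_bins < 5:
        raise ValueError("ON cloud spans fewer than 5 bins along the long axis")
    edges = lo + np.arange(n_bins + 1) * (hi - lo) / n_bins
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, n_bins - 1)

    groups: list[np.ndarray] = []
    pending: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero(idx == b)
        pending.extend(members.tolist())
        if len(pending) >= min_points:
            groups.append(np.array(pending))
            pending = []
    if pending:
        if groups:
            logger.warning(
                "merging %d trailing sparse ON points into the last bin", len(pending)
            )
            groups[-1] = np.concatenate([groups[-1], np.array(pending)])
        else:
            groups.append(np.array(pending))
    if len(groups) < n_bins:
        logger.warning(
            "%d sparse ON bins merged with neighbors", n_bins - len(groups)
        )
    cents = np.array([P[g].mean(axis=0) for g in groups])

    # orient anterior -> posterior
    proj = cents @ axis
    if anterior_point is not None:
        ap = float(np.asarray(anterior_point, float) @ axis)
        anterior_first = abs(proj[0] - ap) < abs(proj[-1] - ap)
    else:
        anterior_first = proj[0] > proj[-1]
    if not anterior_first:
        cents = cents[::-1]
    return cents


def _ray_hull_intersection(
    hull: ConvexHull,
    origin: np.ndarray,
    direction: np.ndarray,
    allow_backtrack: float = 2.0,
) -> tuple[np.ndarray, int] | None:
    """Entry crossing of the line ``origin + t*direction`` into the hull.

    Returns (point, facet index) of the crossing on the ``-direction`` side
    (the entry facet), or None if the line misses. The origin may lie
    slightly inside the hull (a nerve centroid against a noise-dilated globe
    surface): the entry is then at small negative ``t``, accepted up to
    ``allow_backtrack`` mm.
    """
    A = hull.equations[:, :3]
    b = hull.equations[:, 3]
    denom = A @ direction
    num = -(A @ origin + b)
    # inside iff A.x + b <= 0: denom>0 facets bound t above (exit), denom<0
    # facets bound it below (entry)
    t_lo, t_hi = -np.inf, np.inf
    f_lo = -1
    for i in range(len(denom)):
        if abs(denom[i]) < 1e-14:
            if num[i] < 0:
                return None
            continue
        t = num[i] / denom[i]
        if denom[i] > 0:
            t_hi = min(t_hi, t)
        else:
            if t > t_lo:
                t_lo, f_lo = t, i
    if t_lo > t_hi or f_lo < 0 or t_lo < -allow_backtrack:
        return None
    return origin + t_lo * direction, f_lo


def find_on_junction(
    globe_points: np.ndarray,
    centroids: np.ndarray,
    grazing_tol: float = 0.5,
    normal_radius: float = 1.5,
    n_direction_centroids: int = 8,
    surface: str = "hull",
    sphere_radius: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Globe-ON junction and its tangent direction.

    The anterior nerve axis — a total-least-squares line through the most
    anterior ON centroids (``n_direction_centroids`` of them; with 2 this is
    exactly the two-centroid line, but a handful stabilizes the direction
    against bin noise) — is intersected, directed anteriorly, with the
    convex hull of the globe cloud. The junction tangent is the outward
    surface normal at the junction, oriented posteriorly (pointing down the
    nerve); on noisy clouds single hull facets are noise-scale, so the
    normal averages (area-weighted) the facets whose centroid lies within
    ``normal_radius`` of the junction.

    ``surface="sphere"`` intersects the ray with a least-squares sphere
    fitted to the hull vertices instead of the raw facets: on noisy clouds
    this removes the coupling between facet jitter and the obliquely
    incident ray, and the tangent becomes the sphere's outward radial.
    """
    cents = np.asarray(centroids, float)
    if len(cents) < 2:
        raise ValueError("need at least two centroids to aim the junction ray")
    head = cents[: max(2, min(n_direction_centroids, len(cents)))]
    p0, d, _ = fit_line(head)
    if np.dot(d, head[0] - head[-1]) < 0:
        d = -d  # point anteriorly
    # ray origin: foot of the most anterior centroid on the fitted line
    c1 = p0 + np.dot(cents[0] - p0, d) * d
    hull = ConvexHull(np.asarray(globe_points, float).reshape(-1, 3))
    if surface == "sphere":
        cs, rs = _fit_sphere(hull.points[hull.vertices])
        if sphere_radius is not None:
            # the globe is rigid: a radius estimated once and shared across
            # gaze states cancels in strain ratios, unlike per-state fits
            rs = float(sphere_radius)
        w = c1 - cs
        B = w @ d
        C = w @ w - rs * rs
        disc = B * B - C
        if disc < 0:
            raise ValueError(
                f"junction ray misses the fitted globe sphere by "
                f"{np.sqrt(np.abs(C)) - rs:.2f} mm"
            )
        t = -B - np.sqrt(disc)  # entry crossing (posterior surface)
        junction = c1 + t * d
        tangent = (junction - cs) / np.linalg.norm(junction - cs)
        if np.dot(tangent, -d) < 0:
            tangent = -tangent
        return junction, tangent
    hit = _ray_hull_intersection(hull, c1, d)
    if hit is None:
        # grazing or miss: fall back to the nearest hull vertex if close
        verts = hull.points[hull.vertices]
        w = verts - c1
        tproj = np.clip(w @ d, 0, None)
        miss = np.linalg.norm(w - np.outer(tproj, d), axis=1)
        if miss.min() <= grazing_tol:
            logger.warning("junction ray grazes the globe hull; using nearest vertex")
            jv = verts[int(np.argmin(miss))]
            tangent = -d
            return jv, tangent
        raise ValueError(
            f"junction ray misses the globe hull by {miss.min():.2f} mm"
        )
    junction, facet = hit
    centers = hull.points[hull.simplices].mean(axis=1)
    near = np.linalg.norm(centers - junction, axis=1) <= normal_radius
    if not near.any():
        near[facet] = True
    # area-weighted mean of outward facet normals
    tri = hull.points[hull.simplices[near]]
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    normal = (hull.equations[near, :3] * areas[:, None]).sum(axis=0)
    tangent = normal / np.linalg.norm(normal)
    if np.dot(tangent, -d) < 0:
        tangent = -tangent
    return junction, tangent


def _fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit (center, radius)."""
    P = np.asarray(points, float).reshape(-1, 3)
    A = np.c_[2.0 * P, np.ones(len(P))]
    b = np.einsum("ij,ij->i", P, P)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = x[:3]
    r = float(np.sqrt(max(x[3] + c @ c, 0.0)))
    return c, r


def _cone_residuals(params: np.ndarray, pts: np.ndarray) -> np.ndarray:
    vx, vy, vz, az, el, alpha = params
    v = np.array([vx, vy, vz])
    a = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    w = pts - v
    h = w @ a
    rho = np.linalg.norm(w - np.outer(h, a), axis=1)
    return (rho - h * np.tan(alpha)) * np.cos(alpha)


def fit_cone(
    points: np.ndarray,
    axis_init: np.ndarray,
    vertex_init: np.ndarray,
    half_angle_init_deg: float = 25.0,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Least-squares right circular cone: (vertex, unit axis, half-angle deg,
    RMS surface distance)."""
    pts = np.asarray(points, float).reshape(-1, 3)
    a0 = np.asarray(axis_init, float)
    a0 = a0 / np.linalg.norm(a0)
    x0 = np.r_[
        np.asarray(vertex_init, float),
        np.arctan2(a0[1], a0[0]),
        np.arcsin(np.clip(a0[2], -1, 1)),
        np.deg2rad(half_angle_init_deg),
    ]
    sol = least_squares(_cone_residuals, x0, args=(pts,), method="lm", max_nfev=2000)
    vx, vy, vz, az, el, alpha = sol.x
    vertex = np.array([vx, vy, vz])
    axis = np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return vertex, axis, float(np.degrees(abs(alpha))), rms


def find_pseudo_apex(
    line_point: np.ndarray,
    line_dir: np.ndarray,
    wall_points: np.ndarray,
    posterior_fraction: float = 1 / 3,
    max_cone_rms: float = 1.0,
) -> np.ndarray:
    """Pseudo orbital apex: intersection of the straightened-ON line with a
    cone fitted to the posterior portion of the orbital wall.

    ``line_dir`` must point posteriorly (toward the apex). The cone vertex
    region, not reachable in the images, is extrapolated from the posterior
    ``posterior_fraction`` of wall points.
    """
    p = np.asarray(line_point, float).reshape(3)
    d = np.asarray(line_dir, float).reshape(3)
    d = d / np.linalg.norm(d)
    wall = np.asarray(wall_points, float).reshape(-1, 3)
    t = (wall - p) @ d
    cut = np.quantile(t, 1 - posterior_fraction)
    post = wall[t >= cut]
    vertex_init = p + (t.max() + 10.0) * d
    vertex, axis, half_angle, rms = fit_cone(post, -d, vertex_init)
    if rms > max_cone_rms:
        raise ValueError(f"orbital-wall cone fit residual {rms:.2f} mm exceeds limit")
    if axis @ d > 0:  # make the cone open toward the globe
        axis = -axis

    # line-cone intersection: |w|^2 - (1 + tan^2 a)(w.axis)^2 = 0, w = x - vertex
    k2 = 1.0 + np.tan(np.deg2rad(half_angle)) ** 2
    w0 = p - vertex
    M = np.eye(3) - k2 * np.outer(axis, axis)
    A = d @ M @ d
    B = 2.0 * (w0 @ M @ d)
    C = w0 @ M @ w0
    if abs(A) < 1e-12:
        roots = [-C / B] if abs(B) > 1e-12 else []
    else:
        disc = B * B - 4 * A * C
        if disc < -1e-9 * max(1.0, B * B):
            raise ValueError("ON line does not intersect the fitted orbital cone")
        disc = max(disc, 0.0)
        roots = [(-B - np.sqrt(disc)) / (2 * A), (-B + np.sqrt(disc)) / (2 * A)]
    candidates = []
    for t_root in roots:
        x = p + t_root * d
        candidates.append((np.linalg.norm(x - vertex), x))
    if not candidates:
        raise ValueError("degenerate line-cone intersection")
    # the pseudo-apex is the crossing closest to the cone vertex
    return min(candidates, key=lambda c: c[0])[1]


# ---------------------------------------------------------------------------
# parametric curve
# ---------------------------------------------------------------------------


@dataclass
class ONPath:
    """Arc-length parameterized 3D curve from the ON junction to the apex.

    ``s`` below is normalized arc length in [0, 1], measured from the
    junction (s=0) to the apex (s=1) along the fitted curve.
    """

    spline: BSpline  # vector-valued cubic B-spline on t in [0, 1]
    junction: np.ndarray
    apex: np.ndarray
    _t_dense: np.ndarray = field(repr=False, default=None)
    _arc_dense: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        t = np.linspace(0.0, 1.0, 2001)
        pts = self.spline(t)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arc = np.r_[0.0, np.cumsum(seg)]
        self._t_dense = t
        self._arc_dense = arc

    @property
    def length(self) -> float:
        """Total arc length, mm."""
        return float(self._arc_dense[-1])

    def _t_of_s(self, s: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(s, float), 0.0, 1.0)
        return np.interp(s * self.length, self._arc_dense, self._t_dense)

    def point(self, s) -> np.ndarray:
        """Curve point(s) at normalized arc length ``s``."""
        return self.spline(self._t_of_s(s))

    def tangent(self, s) -> np.ndarray:
        """Unit tangent(s) at normalized arc length ``s``."""
        d = self.spline.derivative()(self._t_of_s(s))
        d = np.atleast_2d(d)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        return d[0] if np.isscalar(s) or np.ndim(s) == 0 else d

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.apex - self.junction))


def _project_params(spline: BSpline, pts: np.ndarray, n_dense: int = 2001) -> np.ndarray:
    """Foot-point projection: parameter of the nearest curve point for each pt."""
    t = np.linspace(0.0, 1.0, n_dense)
    curve = spline(t)
    from scipy.spatial import cKDTree

    _, idx = cKDTree(curve).query(pts)
    t0 = t[idx]
    # one parabolic refinement step on the squared distance
    h = 1.0 / (n_dense - 1)
    tm = np.clip(t0 - h, 0, 1)
    tp = np.clip(t0 + h, 0, 1)
    dm = np.sum((spline(tm) - pts) ** 2, axis=1)
    d0 = np.sum((spline(t0) - pts) ** 2, axis=1)
    dp = np.sum((spline(tp) - pts) ** 2, axis=1)
    denom = dm - 2 * d0 + dp
    shift = np.where(np.abs(denom) > 1e-30, 0.5 * (dm - dp) / np.maximum(denom, 1e-30), 0.0)
    return np.clip(t0 + np.clip(shift, -1, 1) * h, 0.0, 1.0)


def fit_on_curve(
    knots: np.ndarray,
    junction_tangent: np.ndarray | None = None,
    max_coefficients: int = 25,
    max_iter: int = 50,
    tol: float = 1e-6,
    tangent_arm: float = 0.5,
) -> ONPath:
    """Least-squares cubic spline through ON knot points.

    ``knots`` must be ordered junction first, apex last. The curve minimizes
    summed squared point-to-curve distances by alternating foot-point
    projection and weighted linear refits; both endpoints are clamped (large
    weights) and, when given, the initial tangent is steered along
    ``junction_tangent`` via a short high-weight arm point.

    Returns the arc-length parameterized :class:`ONPath`; logs a warning if
    the foot-point iteration does not reach ``tol`` mm.
    """
    P = np.asarray(knots, float).reshape(-1, 3)
    if len(P) < 2:
        raise ValueError("need at least 2 knot points")
    junction, apex = P[0].copy(), P[-1].copy()

    fitpts = [P]
    weights = [np.ones(len(P))]
    weights[0][0] = weights[0][-1] = 1e6
    if junction_tangent is not None and len(P) >= 3:
        tg = np.asarray(junction_tangent, float)
        tg = tg / np.linalg.norm(tg)
        fitpts.append((junction + tangent_arm * tg)[None, :])
        weights.append(np.array([1e4]))
    F = np.vstack(fitpts)
    W = np.concatenate(weights)

    # initial parameters: chord length along the ordered knots, arm slotted in
    seg = np.linalg.norm(np.diff(P, axis=0), axis=1)
    t_knots = np.r_[0.0, np.cumsum(seg)]
    t_knots /= t_knots[-1]
    t_par = t_knots.copy()
    if len(F) > len(P):
        t_par = np.r_[t_knots, 0.5 * t_knots[1]]

    k = min(3, len(P) - 1)
    # keep the basis much sparser than the data: dense centroid sets carry
    # sampling noise that an interpolating spline would turn into arc-length
    # inflation; ~6 data points per coefficient smooths it out
    n_coef = int(np.clip(len(P) // 6 + 4, k + 1, min(max_coefficients, len(P))))

    def build_spline(t_par: np.ndarray) -> BSpline:
        order = np.argsort(t_par, kind="stable")
        ts, Fs, Ws = t_par[order], F[order], W[order]
        # deduplicate and renormalize parameters for make_lsq_spline
        ts = ts + np.arange(len(ts)) * 1e-12
        ts = (ts - ts[0]) / (ts[-1] - ts[0])
        if n_coef > k + 1:
            q = np.linspace(0, 1, n_coef - k + 1)[1:-1]
            inner = np.quantile(ts, q)
        else:
            inner = np.array([])
        tk = np.r_[np.zeros(k + 1), inner, np.ones(k + 1)]
        return make_lsq_spline(ts, Fs, tk, k=k, w=Ws)

    spline = build_spline(t_par)
    prev = np.inf
    for _ in range(max_iter):
        t_new = _project_params(spline, F)
        # pin the clamped endpoints to the parameter ends
        t_new[0] = 0.0
        t_new[len(P) - 1] = 1.0
        spline = build_spline(t_new)
        rms = float(
            np.sqrt(np.average(np.sum((spline(t_new) - F) ** 2, axis=1), weights=W))
        )
        if abs(prev - rms) < tol:
            break
        prev = rms
        t_par = t_new
    else:
        logger.warning("fit_on_curve: foot-point iteration did not converge")

    return ONPath(spline, junction, apex)


def tortuosity(path: ONPath) -> float:
    """Arc length divided by the junction-apex chord; 1 for a straight nerve."""
    chord = path.chord
    if chord < 1e-9:
        raise ValueError("zero junction-apex chord")
    return path.length / chord


# ---------------------------------------------------------------------------
# local frames and cross-sections
# ---------------------------------------------------------------------------


def local_frames_along_path(
    path: ONPath,
    junction_x: np.ndarray,
    s_values: np.ndarray,
    min_angle_deg: float = 1.0,
) -> list[Frame]:
    """Per-station frames: Z = curve tangent, X = in-plane projection of the
    junction frame's X axis, Y = Z x X. Successive X axes must not flip."""
    jx = np.asarray(junction_x, float)
    jx = jx / np.linalg.norm(jx)
    frames: list[Frame] = []
    prev_x = None
    for s in np.atleast_1d(s_values):
        Z = path.tangent(float(s))
        proj = jx - np.dot(jx, Z) * Z
        n = np.linalg.norm(proj)
        if n < np.sin(np.deg2rad(min_angle_deg)):
            raise ValueError(
                f"tangent at s={float(s):.3f} is within {min_angle_deg} deg of the "
                "junction X axis; local frame degenerates"
            )
        X = proj / n
        if prev_x is not None and np.dot(prev_x, X) <= 0:
            raise ValueError("local frame X flipped along the path")
        prev_x = X
        frames.append(Frame(path.point(float(s)), X, np.cross(Z, X), Z))
    return frames


@dataclass
class CrossSection:
    """Polar parameterization of one ON cross-section."""

    s: float
    frame: Frame
    thetas: np.ndarray
    r: np.ndarray
    area: float
    n_points: int
    valid: bool = True


def _polar_resample(pts2d: np.ndarray, thetas: np.ndarray) -> np.ndarray | None:
    """Radii of a convex polygon boundary at given polar angles about the
    origin; None if the origin is not inside the hull."""
    try:
        hull = ConvexHull(pts2d)
    except QhullError:
        return None
    verts = pts2d[hull.vertices]  # counterclockwise
    nv = len(verts)
    r = np.empty(len(thetas))
    for i, th in enumerate(thetas):
        u = np.array([np.cos(th), np.sin(th)])
        found = False
        for j in range(nv):
            p1, p2 = verts[j], verts[(j + 1) % nv]
            e = p2 - p1
            denom = u[0] * (-e[1]) - u[1] * (-e[0])
            if abs(denom) < 1e-14:
                continue
            # solve t*u = p1 + s*e, 0<=s<=1, t>0
            t = (p1[0] * (-e[1]) - p1[1] * (-e[0])) / denom
            s_ = (u[0] * p1[1] - u[1] * p1[0]) / denom
            if t > 0 and -1e-9 <= s_ <= 1 + 1e-9:
                r[i] = t
                found = True
                break
        if not found:
            return None
    return r


def cross_sections(
    path: ONPath,
    on_points: np.ndarray,
    n_sections: int = 50,
    n_angles: int = 36,
    junction_x: np.ndarray | None = None,
    slab_halfwidth: float | None = None,
    min_points: int = 6,
    max_radius: float = 4.0,
    s_values: np.ndarray | None = None,
    recenter: bool = True,
) -> list[CrossSection]:
    """Polar cross-sections of the ON cloud at equal-arc-length stations.

    At each station (midpoints of ``n_sections`` equal arc segments) the ON
    points within a slab of half-width one station spacing around the normal
    plane are projected onto that plane; the convex hull boundary is
    resampled at ``n_angles`` equal polar angles in the station frame.
    Stations with too few points, or whose center falls outside the
    projected hull, are marked invalid and excluded downstream.
    """
    P = np.asarray(on_points, float).reshape(-1, 3)
    if s_values is None:
        s_list = (np.arange(n_sections) + 0.5) / n_sections
    else:
        s_list = np.asarray(s_values, float)
        n_sections = len(s_list)
    ds = path.length / n_sections
    if slab_halfwidth is None:
        slab_halfwidth = ds
    if junction_x is None:
        # any direction not parallel to the initial tangent
        t0 = path.tangent(0.0)
        junction_x = np.eye(3)[int(np.argmin(np.abs(t0)))]
    frames = local_frames_along_path(path, junction_x, s_list)
    thetas = 2 * np.pi * np.arange(n_angles) / n_angles

    out: list[CrossSection] = []
    for s, fr in zip(s_list, frames):
        local = fr.to_local(P)
        mask = (np.abs(local[:, 2]) <= slab_halfwidth) & (
            np.hypot(local[:, 0], local[:, 1]) <= max_radius
        )
        sec_pts = local[mask, :2]
        if recenter and len(sec_pts) >= min_points:
            # fitted-curve ripple displaces the nominal center transversely;
            # the slab centroid is the section's own center estimate
            shift = sec_pts.mean(axis=0)
            sec_pts = sec_pts - shift
            fr = Frame(fr.from_local(np.r_[shift, 0.0]), fr.X, fr.Y, fr.Z)
        if len(sec_pts) < min_points:
            logger.warning("station s=%.3f: %d points, marked invalid", s, len(sec_pts))
            out.append(
                CrossSection(float(s), fr, thetas, np.full(n_angles, np.nan), np.nan,
                             len(sec_pts), valid=False)
            )
            continue
        r = _polar_resample(sec_pts, thetas)
        if r is None or np.any(r <= 0):
            logger.warning("station s=%.3f: degenerate boundary, marked invalid", s)
            out.append(
                CrossSection(float(s), fr, thetas, np.full(n_angles, np.nan), np.nan,
                             len(sec_pts), valid=False)
            )
            continue
        # polygon area of the resampled boundary
        x = r * np.cos(thetas)
        y = r * np.sin(thetas)
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        out.append(CrossSection(float(s), fr, thetas, r, float(area), len(sec_pts)))

    # partially sampled slabs (tube ends, oblique truncations) give unreliable
    # boundaries: invalidate stations far below the typical occupancy
    counts = [sec.n_points for sec in out if sec.valid]
    if counts:
        floor = 0.3 * float(np.median(counts))
        for sec in out:
            if sec.valid and sec.n_points < floor:
                logger.warning("station s=%.3f: underfilled slab, marked invalid", sec.s)
                sec.valid = False
    return out


def on_volume(sections: list[CrossSection], path: ONPath) -> float:
    """ON volume: sum of section areas times the equal arc-length segment."""
    valid = [sec for sec in sections if sec.valid]
    if len(valid) < 2:
        raise ValueError("need at least 2 valid cross-sections for a volume")
    ds = path.length / len(sections)
    return float(sum(sec.area for sec in valid) * ds)
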