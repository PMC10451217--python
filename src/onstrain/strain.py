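"""Displacements and Green-Lagrange strain between ON configurations.

Material correspondence uses the tube parameterization: a point is
identified by its normalized arc length ``s`` along the nerve (junction = 0,
apex = 1), its polar angle ``theta`` in the station's local frame, and its
normalized radius ``rho`` (radius divided by the largest radius along that
radial line). Ocular torsion is negligible during horizontal duction, so
``theta`` is matched without a torsional offset.

Displacement gradients on the resulting unstructured grid are reconstructed
from directional derivatives toward the 6 nearest reference neighbors: with
``V`` the 3x6 matrix of unit neighbor directions, each Cartesian axis ``e``
is expressed as ``e = V K`` with ``K = (V^T V)^+ V^T e``, and the gradient
along that axis is the same linear combination of the directional
derivatives. The Green-Lagrange tensor is
``E = (grad u + grad u^T + grad u^T grad u) / 2``; the tangential strain is
its ZZ component in the station frame (Z = path tangent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.spatial import cKDTree

from .ongeometry import CrossSection, ONPath

logger = logging.getLogger(__name__)

REGIONS = ["G1", "G2", "G3", "G4", "G5"]


@dataclass
class ONConfiguration:
    """One gaze state's parameterized nerve: path plus cross-sections."""

    path: ONPath
    sections: list[CrossSection]

    def valid_mask(self) -> np.ndarray:
        return np.array([sec.valid for sec in self.sections])


def _fourier_radius(
    sections: list[CrossSection],
    station_ok: np.ndarray,
    harmonics: int = 2,
    s_window: int = 9,
) -> np.ndarray:
    """Low-order Fourier fit of each section boundary r(theta), with the
    coefficients additionally smoothed along s.

    Convex-hull boundaries of voxelized, noisy clouds are rough at the
    sampling scale; the nerve cross-section is smooth and nearly elliptical,
    so a 2-harmonic series captures it while suppressing jitter that would
    otherwise be amplified by differentiation. Returns the coefficient array
    (n_stations, 2*harmonics+1); invalid stations hold NaN.
    """
    n = len(sections)
    ncoef = 2 * harmonics + 1
    coeffs = np.full((n, ncoef), np.nan)
    for i, sec in enumerate(sections):
        if not station_ok[i]:
            continue
        th = sec.thetas
        cols = [np.ones_like(th)]
        for m in range(1, harmonics + 1):
            cols += [np.cos(m * th), np.sin(m * th)]
        A = np.column_stack(cols)
        coeffs[i], *_ = np.linalg.lstsq(A, sec.r, rcond=None)
    ok = np.flatnonzero(station_ok)
    if len(ok) >= 5:
        win = min(s_window, len(ok) if len(ok) % 2 == 1 else len(ok) - 1)
        if win >= 5:
            coeffs[ok] = savgol_filter(coeffs[ok], win, polyorder=2, axis=0)
    return coeffs


def _radius_at(coeffs_row: np.ndarray, theta: np.ndarray, harmonics: int = 2) -> np.ndarray:
    r = np.full_like(theta, coeffs_row[0], dtype=float)
    for m in range(1, harmonics + 1):
        r += coeffs_row[2 * m - 1] * np.cos(m * theta)
        r += coeffs_row[2 * m] * np.sin(m * theta)
    return r


@dataclass
class MatchedPoints:
    """Material point grid matched across configurations.

    Arrays are flat over (station, angle, shell). ``reference`` and
    ``deformed`` are mm positions in the common registered frame;
    ``tangent`` is the reference station tangent used for tangential strain.
    """

    s: np.ndarray
    theta: np.ndarray
    rho: np.ndarray
    reference: np.ndarray
    deformed: np.ndarray
    tangent: np.ndarray
    station: np.ndarray
    dropped_stations: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.s)


def match_points(
    initial: ONConfiguration,
    deformed: ONConfiguration,
    n_radii: int = 3,
    n_grid_angles: int = 12,
    smooth_boundary: bool = True,
) -> MatchedPoints:
    """Match material points by equal (s, theta, rho) between configurations.

    Both configurations must be parameterized with the same number of
    stations and share junction/apex definitions, in a common registered
    frame. Stations invalid in either configuration are dropped (logged).
    The angular grid for strain sampling is coarser than the boundary
    sampling by default: gradient reconstruction prefers roughly isotropic
    neighbor spacing over dense angular coverage.
    """
    if len(initial.sections) != len(deformed.sections):
        raise ValueError("configurations have different station counts")
    ok = initial.valid_mask() & deformed.valid_mask()
    dropped = np.flatnonzero(~ok).tolist()
    if dropped:
        logger.warning("dropping %d stations invalid in either configuration", len(dropped))
    if not ok.any():
        raise ValueError("no jointly valid stations to match")

    thetas = 2 * np.pi * np.arange(n_grid_angles) / n_grid_angles
    rhos = (np.arange(n_radii) + 1.0) / n_radii

    def boundary_coeffs(cfg: ONConfiguration) -> np.ndarray:
        if smooth_boundary:
            return _fourier_radius(cfg.sections, ok)
        coeffs = np.full((len(cfg.sections), 5), np.nan)
        for i, sec in enumerate(cfg.sections):
            if ok[i]:
                coeffs[i] = 0.0
        return coeffs

    c_init = boundary_coeffs(initial)
    c_def = boundary_coeffs(deformed)

    rows = {k: [] for k in ("s", "theta", "rho", "ref", "defo", "tan", "st")}
    for i in np.flatnonzero(ok):
        sec0, sec1 = initial.sections[i], deformed.sections[i]
        if smooth_boundary:
            r0 = _radius_at(c_init[i], thetas)
            r1 = _radius_at(c_def[i], thetas)
        else:
            r0 = np.interp(thetas, sec0.thetas, sec0.r, period=2 * np.pi)
            r1 = np.interp(thetas, sec1.thetas, sec1.r, period=2 * np.pi)
        if np.any(r0 <= 0) or np.any(r1 <= 0):
            logger.warning("station %d: non-positive smoothed radius, dropped", i)
            dropped.append(i)
            continue
        for rho in rhos:
            d0 = rho * r0
            d1 = rho * r1
            p0 = (
                sec0.frame.origin
                + np.outer(d0 * np.cos(thetas), sec0.frame.X)
                + np.outer(d0 * np.sin(thetas), sec0.frame.Y)
            )
            p1 = (
                sec1.frame.origin
                + np.outer(d1 * np.cos(thetas), sec1.frame.X)
                + np.outer(d1 * np.sin(thetas), sec1.frame.Y)
            )
            rows["s"].append(np.full(n_grid_angles, sec0.s))
            rows["theta"].append(thetas)
            rows["rho"].append(np.full(n_grid_angles, rho))
            rows["ref"].append(p0)
            rows["defo"].append(p1)
            rows["tan"].append(np.tile(sec0.frame.Z, (n_grid_angles, 1)))
            rows["st"].append(np.full(n_grid_angles, i, dtype=int))

    return MatchedPoints(
        s=np.concatenate(rows["s"]),
        theta=np.concatenate(rows["theta"]),
        rho=np.concatenate(rows["rho"]),
        reference=np.vstack(rows["ref"]),
        deformed=np.vstack(rows["defo"]),
        tangent=np.vstack(rows["tan"]),
        station=np.concatenate(rows["st"]),
        dropped_stations=sorted(set(dropped)),
    )


def displacement_field(matched: MatchedPoints) -> np.ndarray:
    """Displacements u = deformed - reference, in the registered frame."""
    if len(matched) == 0:
        raise ValueError("empty match list")
    return matched.deformed - matched.reference


def smooth_displacements(
    matched: MatchedPoints, u: np.ndarray, window: int = 9
) -> np.ndarray:
    """Savitzky-Golay smoothing of u along the nerve, per (theta, rho) line.

    Boundary-extraction jitter is station-local while the true displacement
    field varies on multi-millimetre scales; differentiating unsmoothed
    samples rectifies that jitter into a positive bias of the quadratic
    Green-Lagrange term. Quadratic-preserving smoothing along ``s`` removes
    the jitter without distorting the regional strain profile.
    """
    u = np.asarray(u, float)
    out = u.copy()

    # 1) per-ring angular projection onto Fourier harmonics <= 2: affine and
    # quadratic displacement fields restricted to a circle live exactly in
    # that subspace, so this only removes jitter
    ring = matched.station * 1000 + np.round(matched.rho * 97).astype(int)
    for rid in np.unique(ring):
        m = ring == rid
        th = matched.theta[m]
        if m.sum() < 8:
            continue
        Adm = np.column_stack([
            np.ones_like(th), np.cos(th), np.sin(th),
            np.cos(2 * th), np.sin(2 * th),
        ])
        coef, *_ = np.linalg.lstsq(Adm, out[m], rcond=None)
        out[m] = Adm @ coef

    # 2) quadratic-preserving smoothing along s per (theta, rho) line
    if window >= 5:
        labels = np.round(matched.theta, 9) + 1000 * np.round(matched.rho, 9)
        for lab in np.unique(labels):
            m = labels == lab
            n = int(m.sum())
            win = min(window, n if n % 2 == 1 else n - 1)
            if win < 5:
                continue
            order = np.argsort(matched.s[m], kind="stable")
            idx = np.flatnonzero(m)[order]
            out[idx] = savgol_filter(out[idx], win, polyorder=2, axis=0)
    return out


@dataclass
class GradientReport:
    """Per-point conditioning of the 6-neighbor directional-derivative system."""

    spanning_residual: np.ndarray  # (N, 3) ||V K - e|| per axis
    condition: np.ndarray  # (N,) cond(V^T V) on its range
    flagged: np.ndarray  # (N,) True where the system is unreliable

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


def displacement_gradient(
    points: np.ndarray,
    u: np.ndarray,
    k: int = 6,
    span_tol: float = 1e-6,
    cond_max: float = 1e8,
) -> tuple[np.ndarray, GradientReport]:
    """Displacement gradients from k-nearest-neighbor directional derivatives.

    For each point, unit vectors to its ``k`` nearest reference neighbors
    form the 3 x k matrix V; the directional derivative along neighbor i is
    the forward difference (u_i - u) / |x_i - x|. Each axis e is written as
    e = V K with K = (V^T V)^+ V^T e, and the gradient column for that axis
    is sum_i K_i * (directional derivative_i).

    Exact for affine displacement fields whenever the neighbor vectors span
    3-space. Points whose neighbor system is (near-)coplanar are flagged
    (spanning residual above ``span_tol`` or condition number of V^T V above
    ``cond_max``) and must be excluded from strain summaries.
    """
    X = np.asarray(points, float).reshape(-1, 3)
    U = np.asarray(u, float).reshape(-1, 3)
    n = len(X)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} points")
    tree = cKDTree(X)
    _, nbr = tree.query(X, k=k + 1)
    grads = np.zeros((n, 3, 3))
    resid = np.zeros((n, 3))
    cond = np.zeros(n)
    eye = np.eye(3)
    for i in range(n):
        js = [j for j in nbr[i] if j != i][:k]
        d = X[js] - X[i]
        L = np.linalg.norm(d, axis=1)
        V = (d / L[:, None]).T  # 3 x k
        dd = (U[js] - U[i]) / L[:, None]  # k x 3 directional derivatives
        G = V.T @ V
        Gp = np.linalg.pinv(G, rcond=1e-12)
        K = Gp @ V.T @ eye  # k x 3, one column per axis
        # gradient: d u_p / d x_q = sum_i K[i, q] * dd[i, p]
        grads[i] = dd.T @ K
        resid[i] = np.linalg.norm(V @ K - eye, axis=0)
        sv = np.linalg.svd(V, compute_uv=False)
        cond[i] = np.inf if sv[2] < 1e-12 * sv[0] else (sv[0] / sv[2]) ** 2
    flagged = (resid.max(axis=1) > span_tol) | (cond > cond_max)
    if flagged.any():
        logger.warning("%d/%d neighbor systems flagged as degenerate", flagged.sum(), n)
    return grads, GradientReport(resid, cond, flagged)


def green_lagrange(grad: np.ndarray, compat_no_half: bool = False) -> np.ndarray:
    """Green-Lagrange strain from displacement gradient(s).

    ``E = (grad u + grad u^T + grad u^T . grad u) / 2``; zero for rigid
    motions and matching ``((1+m)^2 - 1)/2`` for a uniaxial stretch ``1+m``.
    ``compat_no_half`` evaluates the sum without the 1/2 factor (a reporting
    convention occasionally seen; not a strain tensor).
    """
    g = np.asarray(grad, float)
    single = g.ndim == 2
    g = g.reshape(-1, 3, 3)
    gT = np.transpose(g, (0, 2, 1))
    E = g + gT + gT @ g
    if not compat_no_half:
        E = 0.5 * E
    return E[0] if single else E


def tangential_strain(E: np.ndarray, z: np.ndarray) -> np.ndarray:
    """ZZ component of E along unit direction(s) z (the local path tangent)."""
    E = np.asarray(E, float)
    z = np.asarray(z, float)
    if E.ndim == 2:
        return float(z @ E @ z)
    if z.ndim == 1:
        z = np.tile(z, (len(E), 1))
    return np.einsum("ni,nij,nj->n", z, E, z)


def regional_summary(
    s: np.ndarray,
    u: np.ndarray,
    e_zz: np.ndarray,
    valid: np.ndarray | None = None,
    n_regions: int = 5,
) -> pd.DataFrame:
    """Mean +/- standard error of |u| and tangential strain in regions of
    initially equal length along the nerve (G1 at the globe ... G5 at the
    apex). Empty regions are reported with n=0 and NaN statistics."""
    s = np.asarray(s, float)
    u_mag = np.linalg.norm(np.asarray(u, float).reshape(-1, 3), axis=1)
    e_zz = np.asarray(e_zz, float)
    if valid is None:
        valid = np.ones(len(s), bool)
    region_idx = np.minimum((s * n_regions).astype(int), n_regions - 1)
    rows = []
    for r in range(n_regions):
        m = (region_idx == r) & valid
        n = int(m.sum())
        if n == 0:
            rows.append({"region": f"G{r + 1}", "n": 0, "mean_u_mag": np.nan,
                         "se_u_mag": np.nan, "mean_Ezz": np.nan, "se_Ezz": np.nan})
            continue
        se = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "region": f"G{r + 1}",
                "n": n,
                "mean_u_mag": float(u_mag[m].mean()),
                "se_u_mag": se(u_mag[m]),
                "mean_Ezz": float(e_zz[m].mean()),
                "se_Ezz": se(e_zz[m]),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sheath diameters
# ---------------------------------------------------------------------------


def sheath_ratios(
    on_area: float, csf_outer_area: float, sheath_outer_area: float
) -> tuple[float, float]:
    """ONS inner/outer diameter ratios relative to the ON diameter.

    Diameters come from best-fit-circle areas, d = 2 sqrt(A / pi); the areas
    must be nested (ON < CSF outer < sheath outer).
    """
    a_on, a_csf, a_ons = map(float, (on_area, csf_outer_area, sheath_outer_area))
    if not (0 < a_on < a_csf < a_ons):
        raise ValueError("areas must be positive and strictly nested (ON < CSF < ONS)")
    d = lambda a: 2.0 * np.sqrt(a / np.pi)
    return d(a_csf) / d(a_on), d(a_ons) / d(a_on)


def _binned_radius(xy: np.ndarray, n_bins: int, quantile: float) -> float | None:
    """Mean over angular bins of a per-bin radius quantile.

    Quantiles are used instead of per-bin extremes: on voxelized, jittered
    boundaries the extremes are noise statistics (biased by the noise tail),
    while an inner/outer quantile tracks the geometric boundary.
    """
    rad = np.hypot(xy[:, 0], xy[:, 1])
    ang = np.arctan2(xy[:, 1], xy[:, 0])
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, ang) - 1, 0, n_bins - 1)
    vals = [np.quantile(rad[which == b], quantile)
            for b in range(n_bins) if (which == b).sum() >= 3]
    if len(vals) < n_bins // 2:
        return None
    return float(np.mean(vals))


def measure_sheath_ratios(
    path: ONPath,
    on_sections: list[CrossSection],
    ons_points: np.ndarray,
    on_points: np.ndarray | None = None,
    n_angle_bins: int = 24,
    s_range: tuple[float, float] = (0.1, 0.6),
) -> tuple[float, float]:
    """Sheath diameter ratios measured from the ON and ONS annulus clouds.

    At each valid ON station within ``s_range``, points in the station slab
    are projected into the section plane. Best-fit circle radii come from
    angular-bin radius quantiles: the ON's outer boundary (high quantile of
    ON radii), the sheath's inner boundary (low quantile of ONS radii, the
    CSF outer margin) and the sheath's outer boundary (high quantile).
    Ratios of the corresponding circle diameters are averaged over stations.
    """
    P = np.asarray(ons_points, float).reshape(-1, 3)
    ds = path.length / len(on_sections)
    inner, outer = [], []
    for sec in on_sections:
        if not sec.valid or not (s_range[0] <= sec.s <= s_range[1]):
            continue
        local = sec.frame.to_local(P)
        m = np.abs(local[:, 2]) <= ds
        if m.sum() < 3 * n_angle_bins:
            continue
        q_lo = _binned_radius(local[m, :2], n_angle_bins, 0.10)
        q_hi = _binned_radius(local[m, :2], n_angle_bins, 0.90)
        if q_lo is None or q_hi is None:
            continue
        # annulus sampled uniformly per area: r_q^2 = r_in^2 + q (r_out^2 -
        # r_in^2), so the two quantiles invert to the boundary circles
        delta = (q_hi**2 - q_lo**2) / 0.8
        r_in = np.sqrt(max(q_lo**2 - 0.1 * delta, 1e-6))
        r_out = np.sqrt(q_hi**2 + 0.1 * delta)
        if on_points is not None:
            loc_on = sec.frame.to_local(np.asarray(on_points, float))
            m_on = np.abs(loc_on[:, 2]) <= ds
            q_on = _binned_radius(loc_on[m_on, :2], n_angle_bins, 0.90)
            if q_on is None:
                continue
            # filled disk: r_q = r sqrt(q)
            r_on = q_on / np.sqrt(0.90)
        else:
            r_on = np.sqrt(sec.area / np.pi)
        ratios = sheath_ratios(np.pi * r_on**2, np.pi * r_in**2, np.pi * r_out**2)
        inner.append(ratios[0])
        outer.append(ratios[1])
    if not inner:
        raise ValueError("no usable stations for sheath measurement")
    return float(np.mean(inner)), float(np.mean(outer))
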