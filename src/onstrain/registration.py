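"""Rigid point-set registration and the Chamfer-based medial plane.

Registration across acquisitions (quasicoronal vs axial) uses the optic
nerve plus the two horizontal rectus muscles: the muscles break the roll
ambiguity of the nearly axisymmetric nerve tube. Registration across gaze
states uses orbital-wall points only, since the bony wall does not move with
the eye.

The registration backend is a trimmed iterative-closest-point (ICP) scheme
with a Kabsch/SVD update, deterministic rotation multi-starts, and symmetric
Chamfer distance as the convergence metric and residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .pointcloud import LABEL_NAMES, Label, LabeledPointCloud
from .transforms import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "RigidTransform",
    "PlaneParams",
    "RegistrationResult",
    "chamfer_distance",
    "rigid_register",
    "register_acquisitions",
    "register_gazes",
    "find_medial_plane",
]


def chamfer_distance(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Chamfer distance between two point sets, in mm.

    Mean nearest-neighbor distance from A to B plus the reverse, halved.
    Zero iff the two sets coincide.
    """
    A = np.asarray(A, float).reshape(-1, 3)
    B = np.asarray(B, float).reshape(-1, 3)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("chamfer_distance requires nonempty point sets")
    dab = cKDTree(B).query(A)[0].mean()
    dba = cKDTree(A).query(B)[0].mean()
    return float(0.5 * (dab + dba))


def _voxel_mean(points: np.ndarray, h: float) -> np.ndarray:
    """Average points within h-sized voxels; suppresses raster structure
    and the outward bias that raw noise extremes impose on convex hulls."""
    P = np.asarray(points, float)
    if h <= 0 or len(P) == 0:
        return P
    idx = np.floor(P / h).astype(np.int64)
    key = idx[:, 0] * 73856093 ^ idx[:, 1] * 19349663 ^ idx[:, 2] * 83492791
    order = np.argsort(key, kind="stable")
    ks = key[order]
    starts = np.flatnonzero(np.r_[True, np.diff(ks) != 0])
    bounds = np.r_[starts, len(ks)]
    Ps = P[order]
    return np.add.reduceat(Ps, bounds[:-1], axis=0) / np.diff(bounds)[:, None]


@dataclass
class RegistrationResult:
    transform: RigidTransform
    residual: float  # symmetric Chamfer after alignment, mm
    converged: bool
    n_iterations: int


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform src -> dst (reflections suppressed)."""
    cs, cd = src.mean(axis=0), dst.mean(axis=0)
    H = (src - cs).T @ (dst - cd)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, cd - R @ cs)


def _icp_single(
    source: np.ndarray,
    target: np.ndarray,
    tree: cKDTree,
    init: RigidTransform,
    trim_fraction: float,
    max_iter: int,
    tol: float,
    symmetric: bool = True,
) -> tuple[RigidTransform, int, bool]:
    """Trimmed ICP with Kabsch updates; symmetric variants match both ways,
    which suppresses the drift that one-way matching shows between clouds of
    unequal sampling density."""
    T = init
    prev = np.inf
    converged = False
    n_keep_s = max(4, int(np.ceil(trim_fraction * len(source))))
    n_keep_t = max(4, int(np.ceil(trim_fraction * len(target))))
    it = 0
    for it in range(1, max_iter + 1):
        moved = T.apply(source)
        d1, i1 = tree.query(moved)
        k1 = np.argsort(d1)[:n_keep_s]
        A, B = moved[k1], target[i1[k1]]
        cost = float(d1[k1].mean())
        if symmetric:
            d2, i2 = cKDTree(moved).query(target)
            k2 = np.argsort(d2)[:n_keep_t]
            A = np.vstack([A, moved[i2[k2]]])
            B = np.vstack([B, target[k2]])
            cost = 0.5 * (cost + float(d2[k2].mean()))
        step = _kabsch(A, B)
        T = step.compose(T)
        if abs(prev - cost) < tol:
            converged = True
            break
        prev = cost
    return T, it, converged


def _estimate_normals(P: np.ndarray, k: int = 12) -> np.ndarray:
    """Unoriented surface normals from k-NN PCA (smallest eigenvector)."""
    tree = cKDTree(P)
    _, idx = tree.query(P, k=k)
    nb = P[idx]  # (n, k, 3)
    nb = nb - nb.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", nb, nb)
    w, v = np.linalg.eigh(cov)
    return v[:, :, 0]


def _point_to_plane_refine(
    source: np.ndarray,
    target: np.ndarray,
    T: RigidTransform,
    trim_fraction: float = 0.8,
    max_iter: int = 40,
    tol: float = 1e-7,
) -> RigidTransform:
    """Gauss-Newton point-to-plane polish of an already-close alignment.

    Minimizes the trimmed sum of squared distances to the target's local
    tangent planes; unlike point-to-point matching it lets correspondences
    slide along the surface, which removes the bias that differing raster
    patterns impose on Chamfer-style costs.
    """
    tree = cKDTree(target)
    normals = _estimate_normals(target)
    n_keep = max(6, int(np.ceil(trim_fraction * len(source))))
    for _ in range(max_iter):
        moved = T.apply(source)
        _, idx = tree.query(moved)
        n = normals[idx]
        r = np.einsum("ij,ij->i", moved - target[idx], n)
        keep = np.argsort(np.abs(r))[:n_keep]
        p, nn, rr = moved[keep], n[keep], r[keep]
        J = np.hstack([np.cross(p, nn), nn])  # d r / d (omega, t)
        x, *_ = np.linalg.lstsq(J, -rr, rcond=None)
        omega, dt = x[:3], x[3:]
        ang = np.linalg.norm(omega)
        step = RigidTransform.from_axis_angle(
            omega if ang > 0 else np.array([0.0, 0, 1.0]),
            np.degrees(ang),
            translation=dt,
        )
        T = step.compose(T)
        if ang < tol and np.linalg.norm(dt) < tol:
            break
    return T


def _pca_inits(src: np.ndarray, tgt: np.ndarray) -> list[RigidTransform]:
    """Principal-axis alignments (four sign variants, reflections excluded).

    The coronal/axial acquisition frames can differ by large rotations, so
    ICP needs a global initializer; moment alignment with Chamfer-based sign
    disambiguation covers it without features."""
    cs, ct = src.mean(axis=0), tgt.mean(axis=0)
    Us = np.linalg.svd((src - cs).T @ (src - cs))[0]
    Ut = np.linalg.svd((tgt - ct).T @ (tgt - ct))[0]
    outs = []
    for s1, s2 in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        for s3 in (1, -1):
            R = Ut @ np.diag([s1, s2, s3]) @ Us.T
            if np.linalg.det(R) > 0:
                outs.append(RigidTransform(R, ct - R @ cs))
                break
    return outs


_PERTURB_ANGLES = [
    (np.array([1.0, 0, 0]), 20.0),
    (np.array([0, 1.0, 0]), 20.0),
    (np.array([0, 0, 1.0]), 20.0),
    (np.array([1.0, 0, 0]), -20.0),
    (np.array([0, 1.0, 0]), -20.0),
    (np.array([0, 0, 1.0]), -20.0),
    (np.array([1.0, 1.0, 1.0]), 30.0),
]


def rigid_register(
    source: np.ndarray,
    target: np.ndarray,
    init: RigidTransform | None = None,
    trim_fraction: float = 0.8,
    max_iter: int = 200,
    tol: float = 1e-6,
    n_starts: int = 8,
    max_points: int = 20000,
    coarse_points: int = 4000,
    seed: int = 0,
    symmetric: bool = True,
    point_to_plane: bool = True,
    denoise_voxel: float | None = None,
) -> RegistrationResult:
    """Trimmed-ICP rigid alignment of ``source`` onto ``target``.

    Multi-start strategy: the given ``init`` (or a centroid-aligning
    translation), four principal-axis alignments, and deterministic rotation
    perturbations are each iterated coarsely on subsampled clouds; the
    winner by symmetric Chamfer distance is then polished on up to
    ``max_points`` points per cloud. Termination: trimmed-cost decrement
    below ``tol`` mm or ``max_iter`` iterations (``converged`` reports it).
    The final residual is the symmetric Chamfer distance on the full inputs.
    """
    source = np.asarray(source, float).reshape(-1, 3)
    target = np.asarray(target, float).reshape(-1, 3)
    if len(source) < 4 or len(target) < 4:
        raise ValueError("rigid_register needs at least 4 points per set")
    full_source, full_target = source, target
    if denoise_voxel:
        # voxel-averaging breaks the raster coherence of gridded
        # acquisitions, whose aligned slice lattices otherwise create false
        # Chamfer minima ("lattice locking"), and suppresses point noise
        source = _voxel_mean(source, denoise_voxel)
        target = _voxel_mean(target, denoise_voxel)

    rng = np.random.default_rng(seed)

    def sub(P: np.ndarray, n: int) -> np.ndarray:
        if len(P) <= n:
            return P
        return P[rng.choice(len(P), n, replace=False)]

    src = sub(source, max_points)
    tgt = sub(target, max_points)
    src_c = sub(src, coarse_points)
    tgt_c = sub(tgt, coarse_points)
    tree_c = cKDTree(tgt_c)

    if init is None:
        init = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    center = src.mean(axis=0)
    starts = [init] + _pca_inits(src_c, tgt_c)
    for axis, ang in _PERTURB_ANGLES[: max(0, n_starts - len(starts))]:
        perturb = RigidTransform.from_axis_angle(axis, ang, center=init.apply(center))
        starts.append(perturb.compose(init))

    best: tuple[float, RigidTransform] | None = None
    for T0 in starts:
        T, _, _ = _icp_single(src_c, tgt_c, tree_c, T0, trim_fraction,
                              min(max_iter, 60), max(tol, 1e-5), symmetric)
        cham = chamfer_distance(T.apply(src_c), tgt_c)
        if best is None or cham < best[0]:
            best = (cham, T)

    tree = cKDTree(tgt)
    T, n_it, conv = _icp_single(src, tgt, tree, best[1], trim_fraction,
                                max_iter, tol, symmetric)
    if point_to_plane:
        T = _point_to_plane_refine(src, tgt, T, trim_fraction)
    # never worse than the initial guess
    if chamfer_distance(init.apply(src), tgt) < chamfer_distance(T.apply(src), tgt):
        T, conv = init, False

    residual = chamfer_distance(T.apply(full_source), full_target)
    if not conv:
        logger.warning("rigid_register did not converge; best residual %.4f mm", residual)
    return RegistrationResult(T, residual, conv, n_it)


def _require_labels(cloud: LabeledPointCloud, labels: list[Label], who: str) -> None:
    present = set(np.unique(cloud.labels).tolist())
    missing = [LABEL_NAMES[int(l)] for l in labels if int(l) not in present]
    if missing:
        raise ValueError(f"{who}: missing required labels {missing}")


def register_acquisitions(
    coronal: LabeledPointCloud,
    axial: LabeledPointCloud,
    **kwargs,
) -> RegistrationResult:
    """Rigid transform mapping the axial acquisition into the coronal frame.

    Runs on the concatenation of ON + LR + MR points only (globe and wall
    excluded): the rectus muscles resolve the roll ambiguity of the
    axisymmetric nerve.
    """
    for cloud, who in ((coronal, "coronal"), (axial, "axial")):
        _require_labels(cloud, [Label.ON, Label.LR, Label.MR], who)
    labs = [Label.ON, Label.LR, Label.MR]
    src = axial.subset(labs).points
    tgt = coronal.subset(labs).points
    return rigid_register(src, tgt, **kwargs)


def register_gazes(
    central: LabeledPointCloud,
    deformed: LabeledPointCloud,
    **kwargs,
) -> RegistrationResult:
    """Rigid transform mapping the deformed-gaze session onto central gaze.

    Uses orbital-wall points only: the bony wall is not displaced by eye
    rotation, so it anchors the inter-session alignment.
    """
    _require_labels(central, [Label.ORBITAL_WALL], "central")
    _require_labels(deformed, [Label.ORBITAL_WALL], "deformed")
    src = deformed.select(Label.ORBITAL_WALL)
    tgt = central.select(Label.ORBITAL_WALL)
    return rigid_register(src, tgt, **kwargs)


# ---------------------------------------------------------------------------
# medial plane
# ---------------------------------------------------------------------------


@dataclass
class PlaneParams:
    """Plane ``normal . x = offset`` with a unit normal."""

    normal: np.ndarray
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("zero plane normal")
        self.normal = n / norm
        self.offset = float(self.offset)

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.normal - self.offset

    def reflect(self, points: np.ndarray) -> np.ndarray:
        d = self.signed_distance(points)
        return np.asarray(points, float) - 2.0 * d[:, None] * self.normal

    def to_dict(self) -> dict:
        return {"normal": self.normal.tolist(), "offset": self.offset}

    @classmethod
    def from_dict(cls, d: dict) -> "PlaneParams":
        return cls(np.asarray(d["normal"]), d["offset"])


def _plane_from_angles(az: float, el: float, offset: float) -> PlaneParams:
    n = np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    return PlaneParams(n, offset)


def find_medial_plane(
    left_wall: np.ndarray,
    right_wall: np.ndarray,
    max_points: int = 3000,
    seed: int = 0,
) -> PlaneParams:
    """Mirror-symmetry plane between the two orbits' wall clouds.

    The plane is parameterized by its normal direction (azimuth, elevation)
    and offset; Nelder–Mead minimizes the symmetric Chamfer distance between
    the reflected left cloud and the right cloud, seeded by the perpendicular
    bisector plane of the two centroids.
    """
    left = np.asarray(left_wall, float).reshape(-1, 3)
    right = np.asarray(right_wall, float).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    if len(left) > max_points:
        left = left[rng.choice(len(left), max_points, replace=False)]
    if len(right) > max_points:
        right = right[rng.choice(len(right), max_points, replace=False)]

    cl, cr = left.mean(axis=0), right.mean(axis=0)
    n0 = cr - cl
    if np.linalg.norm(n0) < 1e-9:
        n0 = np.array([1.0, 0.0, 0.0])
    n0 = n0 / np.linalg.norm(n0)
    az0 = float(np.arctan2(n0[1], n0[0]))
    el0 = float(np.arcsin(np.clip(n0[2], -1, 1)))
    off0 = float(0.5 * (cl + cr) @ n0)
    tree_r = cKDTree(right)

    def cost(x: np.ndarray) -> float:
        plane = _plane_from_angles(*x)
        refl = plane.reflect(left)
        return 0.5 * (
            tree_r.query(refl)[0].mean() + cKDTree(refl).query(right)[0].mean()
        )

    res = minimize(
        cost,
        np.array([az0, el0, off0]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 2000},
    )
    plane = _plane_from_angles(*res.x)
    if not res.success:
        raise RuntimeError(
            f"medial-plane optimization failed (final Chamfer {res.fun:.4f} mm, "
            f"normal {plane.normal}, offset {plane.offset:.3f})"
        )
    return plane
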