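"""Labeled point clouds and label-mask image stacks.

Conventions
-----------
All coordinates are millimetres, right-handed. An :class:`ImageStack` lives in
its acquisition frame: the voxel with index ``(i, j, k)`` has its *center* at
``origin + index * spacing`` along the stack's axes. Slices are stacked along
axis 2 (``k``), which for quasicoronal acquisitions is the long orbital axis.

Label vocabulary: globe, ON (optic nerve), ONS (optic nerve sheath), LR
(lateral rectus), MR (medial rectus), orbital wall. 0 is background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

logger = logging.getLogger(__name__)


class Label(IntEnum):
    GLOBE = 1
    ON = 2
    ONS = 3
    LR = 4
    MR = 5
    ORBITAL_WALL = 6


LABEL_NAMES = {int(l): l.name.lower() for l in Label}


@dataclass
class LabeledPointCloud:
    """N x 3 points (mm) with per-point anatomical labels and a frame tag."""

    points: np.ndarray
    labels: np.ndarray
    frame: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
        if len(self.points) != len(self.labels):
            raise ValueError("points and labels length mismatch")
        if len(self.points) == 0:
            raise ValueError("empty point cloud")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates in point cloud")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, label: int) -> np.ndarray:
        """Points carrying ``label`` as an (M, 3) array."""
        return self.points[self.labels == int(label)]

    def subset(self, labels: list[int], frame: str | None = None) -> "LabeledPointCloud":
        mask = np.isin(self.labels, [int(l) for l in labels])
        if not mask.any():
            missing = [LABEL_NAMES.get(int(l), str(l)) for l in labels]
            raise ValueError(f"no points with labels {missing}")
        return LabeledPointCloud(
            self.points[mask], self.labels[mask], frame or self.frame
        )

    def counts(self) -> dict[int, int]:
        vals, cnt = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    def transformed(self, transform, frame: str | None = None) -> "LabeledPointCloud":
        return LabeledPointCloud(
            transform.apply(self.points), self.labels.copy(), frame or self.frame
        )

    @classmethod
    def concatenate(
        cls, clouds: list["LabeledPointCloud"], frame: str | None = None
    ) -> "LabeledPointCloud":
        return cls(
            np.vstack([c.points for c in clouds]),
            np.concatenate([c.labels for c in clouds]),
            frame or clouds[0].frame,
        )


@dataclass
class ImageStack:
    """Integer label volume with voxel spacing and acquisition-frame metadata."""

    volume: np.ndarray  # (nx, ny, nk) int, 0 = background
    spacing: np.ndarray  # (3,) mm
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    frame: str = "unknown"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (voxel centers)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx, float) * self.spacing + self.origin


def masks_to_points(stack: ImageStack) -> LabeledPointCloud:
    """Convert labeled voxels to one point per voxel at the voxel center."""
    idx = np.argwhere(stack.volume != 0)
    if len(idx) == 0:
        raise ValueError("image stack contains no labeled voxels")
    pts = idx * stack.spacing + stack.origin
    labels = stack.volume[idx[:, 0], idx[:, 1], idx[:, 2]]
    return LabeledPointCloud(pts, labels, stack.frame)


def voxelize(
    cloud: LabeledPointCloud,
    spacing: np.ndarray,
    origin: np.ndarray | None = None,
    frame: str | None = None,
) -> ImageStack:
    """Bin points into a voxel grid; each voxel takes the majority label.

    The grid is anchored so that voxel centers lie at
    ``origin + index * spacing``; if ``origin`` is omitted, it is chosen as the
    (per-axis) minimum point coordinate, so points already on a grid map back
    to exact voxel centers.
    """
    spacing = np.asarray(spacing, dtype=float).reshape(3)
    if np.any(spacing <= 0):
        raise ValueError("spacing must be positive")
    pts = cloud.points
    if origin is None:
        origin = pts.min(axis=0)
    origin = np.asarray(origin, dtype=float).reshape(3)
    idx = np.rint((pts - origin) / spacing).astype(int)
    shape = idx.max(axis=0) + 1
    vol = np.zeros(tuple(shape), dtype=np.int16)
    # majority label per voxel
    flat = np.ravel_multi_index(tuple(idx.T), tuple(shape))
    order = np.argsort(flat, kind="stable")
    flat_s, lab_s = flat[order], cloud.labels[order]
    starts = np.flatnonzero(np.r_[True, np.diff(flat_s) != 0])
    bounds = np.r_[starts, len(flat_s)]
    for a, b in zip(bounds[:-1], bounds[1:]):
        labs, cnts = np.unique(lab_s[a:b], return_counts=True)
        vol[np.unravel_index(flat_s[a], tuple(shape))] = labs[np.argmax(cnts)]
    return ImageStack(vol, spacing, origin, frame or cloud.frame)


# ---------------------------------------------------------------------------
# slice interpolation
# ---------------------------------------------------------------------------


def _signed_distance(mask: np.ndarray, spacing2d: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance of a 2D mask (negative inside)."""
    if mask.any():
        d_out = distance_transform_edt(~mask, sampling=spacing2d)
        d_in = distance_transform_edt(mask, sampling=spacing2d)
        return d_out - d_in
    return np.full(mask.shape, np.inf)


def interpolate_slices(stack: ImageStack, factor: int, axis: int = 2) -> ImageStack:
    """Shape-based interpolation of label slices along the stacking axis.

    Per-label signed distance maps of flanking slices are linearly
    interpolated and thresholded at zero; where several labels claim a voxel,
    the label with the most negative interpolated distance wins. Original
    slices are reproduced exactly at their positions. A label present in only
    one slice of a flanking pair leaves that gap empty (logged).
    """
    if factor < 2:
        raise ValueError("interpolation factor must be >= 2")
    if axis != 2:
        vol = np.moveaxis(stack.volume, axis, 2)
        sp = stack.spacing.copy()
        sp[[axis, 2]] = sp[[2, axis]]
        orig = stack.origin.copy()
        orig[[axis, 2]] = orig[[2, axis]]
        tmp = interpolate_slices(ImageStack(vol, sp, orig, stack.frame), factor, axis=2)
        vol2 = np.moveaxis(tmp.volume, 2, axis)
        sp2 = tmp.spacing.copy()
        sp2[[axis, 2]] = sp2[[2, axis]]
        or2 = tmp.origin.copy()
        or2[[axis, 2]] = or2[[2, axis]]
        return ImageStack(vol2, sp2, or2, stack.frame)

    vol = stack.volume
    n = vol.shape[2]
    labels = [int(l) for l in np.unique(vol) if l != 0]
    n_out = (n - 1) * factor + 1 if n > 1 else 1
    out = np.zeros(vol.shape[:2] + (n_out,), dtype=vol.dtype)
    out[:, :, ::factor] = vol
    sp2d = stack.spacing[:2]

    if n == 1:
        logger.warning("single-slice stack: interpolation is a no-op")
        return ImageStack(out, np.r_[stack.spacing[:2], stack.spacing[2] / factor],
                          stack.origin, stack.frame)

    for k in range(n - 1):
        a, b = vol[:, :, k], vol[:, :, k + 1]
        sd_pair = {}
        for lab in labels:
            ma, mb = a == lab, b == lab
            if ma.any() != mb.any():
                logger.warning(
                    "label %s present on only one side of slice gap %d; gap left empty",
                    LABEL_NAMES.get(lab, lab), k,
                )
                continue
            if not ma.any():
                continue
            sd_pair[lab] = (_signed_distance(ma, sp2d), _signed_distance(mb, sp2d))
        for m in range(1, factor):
            t = m / factor
            best_sd = np.full(vol.shape[:2], np.inf)
            best_lab = np.zeros(vol.shape[:2], dtype=vol.dtype)
            for lab, (sda, sdb) in sd_pair.items():
                sd = (1 - t) * sda + t * sdb
                take = (sd < 0) & (sd < best_sd)
                best_sd[take] = sd[take]
                best_lab[take] = lab
            out[:, :, k * factor + m] = best_lab

    new_spacing = stack.spacing.copy()
    new_spacing[2] /= factor
    return ImageStack(out, new_spacing, stack.origin, stack.frame)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_cloud(cloud: LabeledPointCloud, path: str | Path) -> None:
    """Write a labeled cloud to .ply (ascii) or .csv, chosen by extension."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            {
                "x": cloud.points[:, 0],
                "y": cloud.points[:, 1],
                "z": cloud.points[:, 2],
                "label": cloud.labels,
            }
        ).to_csv(path, index=False, float_format="%.9g")
    elif path.suffix.lower() == ".ply":
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"comment frame {cloud.frame}\n"
                f"element vertex {len(cloud)}\n"
                "property double x\nproperty double y\nproperty double z\n"
                "property int label\nend_header\n"
            )
            for p, l in zip(cloud.points, cloud.labels):
                fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g} {int(l)}\n")
    else:
        raise ValueError(f"unsupported cloud format: {path.suffix}")


def read_cloud(path: str | Path, frame: str | None = None) -> LabeledPointCloud:
    """Read a labeled cloud from .ply (ascii, with an integer ``label``
    vertex property) or .csv (columns x, y, z, label in any order)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        for col in ("x", "y", "z", "label"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing required column '{col}'")
        return LabeledPointCloud(
            df[["x", "y", "z"]].to_numpy(float),
            df["label"].to_numpy(int),
            frame or "file",
        )
    if path.suffix.lower() == ".ply":
        return _read_ply(path, frame)
    raise ValueError(f"unsupported cloud format: {path.suffix}")


def _read_ply(path: Path, frame: str | None) -> LabeledPointCloud:
    props: list[str] = []
    n_vertex = None
    file_frame = None
    with open(path) as fh:
        line = fh.readline().strip()
        if line != "ply":
            raise ValueError(f"{path}: not a PLY file")
        fmt = fh.readline().strip()
        if "ascii" not in fmt:
            raise ValueError(f"{path}: only ascii PLY is supported")
        for line in fh:
            line = line.strip()
            if line.startswith("comment frame "):
                file_frame = line.split("comment frame ", 1)[1]
            elif line.startswith("element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith("element") and n_vertex is not None:
                raise ValueError(f"{path}: unexpected extra element after vertices")
            elif line.startswith("property"):
                props.append(line.split()[-1])
            elif line == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: no vertex element in header")
        for col in ("x", "y", "z", "label"):
            if col not in props:
                raise ValueError(f"{path}: missing vertex property '{col}'")
        cols = {name: props.index(name) for name in ("x", "y", "z", "label")}
        data = np.loadtxt(fh, max_rows=n_vertex, ndmin=2)
    pts = data[:, [cols["x"], cols["y"], cols["z"]]]
    labels = data[:, cols["label"]].astype(int)
    return LabeledPointCloud(pts, labels, frame or file_frame or "file")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a label stack as NIfTI; spacing and origin go in the affine."""
    import nibabel as nib

    img = nib.Nifti1Image(stack.volume.astype(np.int16), stack.affine)
    nib.save(img, str(path))


def read_stack(path: str | Path, frame: str = "file") -> ImageStack:
    """Read a NIfTI label stack written by :func:`write_stack` (axis-aligned
    affine; voxel (0,0,0) center at the affine translation)."""
    import nibabel as nib

    img = nib.load(str(path))
    A = img.affine
    off = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    if not np.allclose(off, 0, atol=1e-6):
        raise ValueError(f"{path}: only axis-aligned label stacks are supported")
    return ImageStack(
        np.asarray(img.dataobj).astype(np.int16),
        np.diag(A[:3, :3]),
        A[:3, 3],
        frame,
    )
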