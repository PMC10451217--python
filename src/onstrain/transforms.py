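"""Proper rigid transforms (rotation + translation) in millimetre coordinates.

Rotations are 3x3 proper orthogonal matrices (no reflections); transforms map
points from one frame to another as ``x' = R @ x + t``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``x -> rotation @ x + translation``.

    Parameters
    ----------
    rotation
        3x3 proper orthogonal matrix (``R.T @ R = I``, ``det R = +1``).
    translation
        3-vector in mm.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has det = -1 (reflection not allowed)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_deg: float,
        center: np.ndarray | None = None,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Rotation by ``angle_deg`` about ``axis``.

        If ``center`` is given, the rotation is about the line through
        ``center``; an extra ``translation`` may be appended.
        """
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("zero rotation axis")
        k = axis / n
        th = np.deg2rad(angle_deg)
        K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        t = np.zeros(3) if translation is None else np.asarray(translation, float)
        if center is not None:
            c = np.asarray(center, dtype=float)
            t = t + c - R @ c
        return cls(R, t)

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array or a single 3-vector."""
        p = np.asarray(points, dtype=float)
        if p.ndim == 1:
            return self.rotation @ p + self.translation
        return p @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    # -- diagnostics -------------------------------------------------------
    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def rotation_axis(self) -> np.ndarray:
        """Unit rotation axis (arbitrary for the identity)."""
        w, v = np.linalg.eig(self.rotation)
        i = int(np.argmin(np.abs(w - 1.0)))
        axis = np.real(v[:, i])
        n = np.linalg.norm(axis)
        return axis / n if n > 0 else np.array([0.0, 0.0, 1.0])

    def difference_from(self, other: "RigidTransform") -> tuple[float, float]:
        """(rotation deg, translation mm) discrepancy between two transforms."""
        d = self.compose(other.inverse())
        return d.rotation_angle_deg(), float(np.linalg.norm(d.translation))

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        return cls.from_dict(json.loads(Path(path).read_text()))


def rotation_between(a: np.ndarray, b: np.ndarray) -> RigidTransform:
    """Minimal rotation mapping unit direction ``a`` onto unit direction ``b``."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    s = np.linalg.norm(v)
    c = float(np.dot(a, b))
    if s < 1e-15:
        if c > 0:
            return RigidTransform.identity()
        # antiparallel: rotate 180 deg about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return RigidTransform.from_axis_angle(axis, 180.0)
    angle = np.degrees(np.arctan2(s, c))
    return RigidTransform.from_axis_angle(v, angle)
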