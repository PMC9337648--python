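"""Rigid transforms mapping image-plane / phantom coordinates to world mm."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = ["RigidTransform", "random_small_rotation", "rotation_from_rotvec_deg"]


@dataclass(frozen=True)
class RigidTransform:
    """p_world = R @ p_local + t, lengths in millimetres."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform an (..., 3) array of points."""
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply `other` first."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def quaternion(self) -> np.ndarray:
        """Rotation as (qx, qy, qz, qw) unit quaternion."""
        return Rotation.from_matrix(self.rotation).as_quat()

    @classmethod
    def from_quaternion(cls, quat: np.ndarray, translation: np.ndarray) -> "RigidTransform":
        return cls(Rotation.from_quat(np.asarray(quat, dtype=float)).as_matrix(), translation)


def rotation_from_rotvec_deg(rotvec_deg: np.ndarray) -> np.ndarray:
    """Rotation matrix from a rotation vector whose norm is the angle in degrees."""
    return Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float), degrees=True).as_matrix()


def random_small_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    """Uniform random axis, uniform angle in [0, max_angle_deg]."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    return rotation_from_rotvec_deg(axis * angle)
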