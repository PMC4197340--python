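"""Rigid 6-DOF transforms (rotation + translation) in millimetres.

A :class:`RigidPose` maps model coordinates into lab/camera coordinates,
``x_lab = R @ x_model + t``.  Composition is written left-to-right in
application order: ``(A @ B)(x) == A(B(x))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ContractViolationError

_ORTHO_TOL = 1e-8


def _check_rotation(R: np.ndarray, tol: float = _ORTHO_TOL) -> None:
    if R.shape != (3, 3):
        raise ContractViolationError(f"rotation must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ContractViolationError("rotation is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ContractViolationError("rotation is a reflection (det < 0)")


@dataclass(frozen=True)
class RigidPose:
    """Proper rigid transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    _skip_check: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not self._skip_check:
            _check_rotation(R)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -----------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidPose":
        return cls(np.eye(3), np.zeros(3), _skip_check=True)

    @classmethod
    def from_euler_deg(cls, angles_deg, translation) -> "RigidPose":
        """Pose from extrinsic x-y-z Euler angles in degrees.

        This is the parameterisation used throughout registration I/O:
        columns (rx, ry, rz, tx, ty, tz).
        """
        R = Rotation.from_euler("xyz", np.asarray(angles_deg, float),
                                degrees=True).as_matrix()
        return cls(R, translation, _skip_check=True)

    @classmethod
    def from_params(cls, params) -> "RigidPose":
        p = np.asarray(params, dtype=float).reshape(6)
        return cls.from_euler_deg(p[:3], p[3:])

    # -- algebra ----------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Return ``self ∘ other`` (apply ``other`` first)."""
        return RigidPose(self.rotation @ other.rotation,
                         self.rotation @ other.translation + self.translation,
                         _skip_check=True)

    def __matmul__(self, other: "RigidPose") -> "RigidPose":
        return self.compose(other)

    def inverse(self) -> "RigidPose":
        Rt = self.rotation.T
        return RigidPose(Rt, -Rt @ self.translation, _skip_check=True)

    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    # -- parameter views --------------------------------------------------
    def euler_deg(self) -> np.ndarray:
        """Extrinsic x-y-z Euler angles, degrees."""
        return Rotation.from_matrix(self.rotation).as_euler("xyz", degrees=True)

    def params(self) -> np.ndarray:
        """(rx, ry, rz, tx, ty, tz) with rotations in degrees."""
        return np.concatenate([self.euler_deg(), self.translation])

    def perturbed(self, rng: np.random.Generator, max_rot_deg: float,
                  max_trans_mm: float) -> "RigidPose":
        """Seeded uniform perturbation, ±max per rotation/translation axis."""
        dr = rng.uniform(-max_rot_deg, max_rot_deg, 3)
        dt = rng.uniform(-max_trans_mm, max_trans_mm, 3)
        dR = Rotation.from_euler("xyz", dr, degrees=True).as_matrix()
        return RigidPose(dR @ self.rotation, self.translation + dt,
                         _skip_check=True)

    def allclose(self, other: "RigidPose", atol: float = 1e-9) -> bool:
        return (np.allclose(self.rotation, other.rotation, atol=atol)
                and np.allclose(self.translation, other.translation, atol=atol))


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle between two rotation matrices, degrees."""
    cosang = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
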