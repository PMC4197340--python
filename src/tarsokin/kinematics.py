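"""Joint-coordinate-system (JCS) angles for the talocrural and subtalar joints.

The talocrural joint is the motion of the talus relative to the tibia; the
subtalar joint is the motion of the calcaneus relative to the talus.  Angles
follow the Grood–Suntay convention: flexion about the parent-frame
mediolateral (Z) axis, axial rotation about the child-frame proximodistal
(Y) axis, and inversion/eversion about the mutually perpendicular floating
axis.  With right-foot frames (X anterior, Y proximal, Z lateral) this is an
intrinsic Z–X–Y Euler factorisation ``R = Rz(a) Rx(b) Ry(c)`` with

* dorsiflexion(+) / plantarflexion(−) = ``a``
* eversion(+) / inversion(−)          = ``-b``
* external(+) / internal(−) rotation  = ``-c``

Angles are reported in degrees, relative to a static standing reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .anatomy import AnatomicalFrame
from .errors import ContractViolationError, TarsokinError
from .rigid import RigidPose

__all__ = [
    "JointDefinition", "TALOCRURAL", "SUBTALAR", "JointAngleSeries",
    "AngularChange", "GimbalWarning",
    "anatomical_placement", "relative_pose", "jcs_decompose", "jcs_compose",
    "zero_to_reference", "angular_change", "series_from_poses",
]

AXES = ("dorsiflexion", "eversion", "external_rotation")


class GimbalWarning(UserWarning):
    """The floating axis is near-degenerate (flexion axis ≈ long axis)."""


@dataclass(frozen=True)
class JointDefinition:
    name: str
    parent: str
    child: str

    def __post_init__(self) -> None:
        valid = {("talocrural", "tibia", "talus"),
                 ("subtalar", "talus", "calcaneus")}
        if (self.name, self.parent, self.child) not in valid:
            raise ContractViolationError(
                f"invalid joint definition {(self.name, self.parent, self.child)}")


TALOCRURAL = JointDefinition("talocrural", "tibia", "talus")
SUBTALAR = JointDefinition("subtalar", "talus", "calcaneus")


@dataclass
class JointAngleSeries:
    """Per-frame JCS angles for one joint, time in ms relative to toe contact."""

    joint: str
    time_ms: np.ndarray
    dorsiflexion: np.ndarray
    eversion: np.ndarray
    external_rotation: np.ndarray
    missing: np.ndarray = field(default=None)   # bool mask of unusable frames

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        for ax in AXES:
            setattr(self, ax, np.asarray(getattr(self, ax), dtype=float))
            if getattr(self, ax).shape != self.time_ms.shape:
                raise ContractViolationError("angle/time length mismatch")
        if self.missing is None:
            self.missing = np.zeros(self.time_ms.shape, dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    def axis(self, name: str) -> np.ndarray:
        if name not in AXES:
            raise KeyError(name)
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ms": self.time_ms, "joint": self.joint,
            "dorsiflexion_deg": self.dorsiflexion,
            "eversion_deg": self.eversion,
            "external_rotation_deg": self.external_rotation,
            "missing": self.missing,
        })


@dataclass(frozen=True)
class AngularChange:
    """Per-axis angle change over a named period of the landing."""

    joint: str
    period: str
    dorsiflexion: float
    eversion: float
    external_rotation: float


# ---------------------------------------------------------------------------
# rigid algebra
# ---------------------------------------------------------------------------

def anatomical_placement(pose: RigidPose, frame: AnatomicalFrame) -> RigidPose:
    """Rigid map anatomical coords → lab, for a bone at ``pose``."""
    return pose @ frame.to_pose().inverse()


def relative_pose(parent_pose: RigidPose, parent_frame: AnatomicalFrame,
                  child_pose: RigidPose, child_frame: AnatomicalFrame) -> RigidPose:
    """Child anatomical frame expressed in the parent anatomical frame."""
    parent_lab = anatomical_placement(parent_pose, parent_frame)
    child_lab = anatomical_placement(child_pose, child_frame)
    return parent_lab.inverse() @ child_lab


# ---------------------------------------------------------------------------
# JCS decomposition
# ---------------------------------------------------------------------------

_GIMBAL_MARGIN_DEG = 2.0


def jcs_decompose(rel: RigidPose, joint: JointDefinition = TALOCRURAL,
                  side: str = "right"):
    """JCS angles (dorsiflexion, eversion, external rotation), degrees.

    ``rel`` is the child anatomical frame in parent anatomical coordinates.
    Near gimbal lock (floating axis undefined) a :class:`GimbalWarning` is
    issued and the angles are still returned.
    """
    if side != "right":
        raise ContractViolationError("only right-foot conventions are supported")
    a, b, c = Rotation.from_matrix(rel.rotation).as_euler("ZXY", degrees=True)
    if 90.0 - abs(b) < _GIMBAL_MARGIN_DEG:
        warnings.warn(
            f"{joint.name}: flexion axis within {_GIMBAL_MARGIN_DEG} deg of the "
            "long axis; floating-axis angles are ill-conditioned", GimbalWarning)
    return float(a), float(-b), float(-c)


def jcs_compose(dorsiflexion: float, eversion: float, external_rotation: float,
                translation=(0.0, 0.0, 0.0)) -> RigidPose:
    """Forward JCS map: build the child-in-parent pose from JCS angles (deg)."""
    R = Rotation.from_euler(
        "ZXY", [dorsiflexion, -eversion, -external_rotation],
        degrees=True).as_matrix()
    return RigidPose(R, np.asarray(translation, dtype=float), _skip_check=True)


# ---------------------------------------------------------------------------
# series operations
# ---------------------------------------------------------------------------

def zero_to_reference(series: JointAngleSeries, reference) -> JointAngleSeries:
    """Subtract the static-reference angles so the standing posture reads 0°.

    ``reference`` is a 3-sequence (dorsiflexion, eversion, external rotation).
    """
    ref = np.asarray(reference, dtype=float).reshape(3)
    return JointAngleSeries(
        joint=series.joint, time_ms=series.time_ms.copy(),
        dorsiflexion=series.dorsiflexion - ref[0],
        eversion=series.eversion - ref[1],
        external_rotation=series.external_rotation - ref[2],
        missing=series.missing.copy(),
    )


def _interp(series: JointAngleSeries, axis: str, t: float) -> float:
    tt, val = series.time_ms, series.axis(axis)
    ok = ~series.missing
    return float(np.interp(t, tt[ok], val[ok]))


def angular_change(series: JointAngleSeries, t_start_ms: float,
                   t_end_ms: float, period: str = "") -> AngularChange:
    """Angle(end) − angle(start) per axis, linearly interpolating the 60 Hz
    series at the period boundaries."""
    if not t_start_ms < t_end_ms:
        raise ContractViolationError("t_start must precede t_end")
    lo, hi = series.time_ms[0], series.time_ms[-1]
    if t_start_ms < lo - 1e-9 or t_end_ms > hi + 1e-9:
        raise ContractViolationError(
            f"period [{t_start_ms}, {t_end_ms}] ms outside series window [{lo}, {hi}]")
    deltas = {ax: _interp(series, ax, t_end_ms) - _interp(series, ax, t_start_ms)
              for ax in AXES}
    return AngularChange(joint=series.joint, period=period, **deltas)


def series_from_poses(
    poses: Dict[str, Sequence[Optional[RigidPose]]],
    frames: Dict[str, AnatomicalFrame],
    time_ms: np.ndarray,
    joints: Sequence[JointDefinition] = (TALOCRURAL, SUBTALAR),
    reference: Optional[Dict[str, Sequence[float]]] = None,
) -> Dict[str, JointAngleSeries]:
    """Per-frame JCS angle series for each joint.

    ``poses`` maps bone name → per-frame poses (``None`` marks a frame where
    registration failed for that bone).  Single-frame gaps are linearly
    interpolated; longer gaps are flagged missing in the output series.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    n = len(time_ms)
    out: Dict[str, JointAngleSeries] = {}
    for joint in joints:
        for bone in (joint.parent, joint.child):
            if bone not in poses or len(poses[bone]) != n:
                raise ContractViolationError(
                    f"poses for {bone!r} missing or not on the common frame grid")
        angles = np.full((n, 3), np.nan)
        for k in range(n):
            pp, cp = poses[joint.parent][k], poses[joint.child][k]
            if pp is None or cp is None:
                continue
            rel = relative_pose(pp, frames[joint.parent], cp, frames[joint.child])
            angles[k] = jcs_decompose(rel, joint)
        missing = np.isnan(angles[:, 0])
        # interpolate over single-frame gaps only
        filled = angles.copy()
        for k in np.flatnonzero(missing):
            if 0 < k < n - 1 and not missing[k - 1] and not missing[k + 1]:
                filled[k] = 0.5 * (angles[k - 1] + angles[k + 1])
        still_missing = np.isnan(filled[:, 0])
        filled[still_missing] = 0.0
        series = JointAngleSeries(
            joint=joint.name, time_ms=time_ms,
            dorsiflexion=filled[:, 0], eversion=filled[:, 1],
            external_rotation=filled[:, 2], missing=still_missing)
        if reference is not None and joint.name in reference:
            series = zero_to_reference(series, reference[joint.name])
        out[joint.name] = series
    return out
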