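"""Force-plate synchronization, landing-event detection and analysis windows.

The landing is a forefoot landing: the forefoot touches first (toe contact,
detected from the vertical ground reaction force), the heel follows (heel
contact, detected kinematically from the calcaneus because a forefoot
landing produces no second force onset).  All reporting uses a clock with
t = 0 at toe contact; the analysed window runs from 33 ms before to 250 ms
after toe contact, with an intermediate mark at +150 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .anatomy import TriMesh
from .errors import (ContractViolationError, NoContactError,
                     SynchronizationError)
from .rigid import RigidPose

__all__ = [
    "ForcePlateRecord", "TrialEvents", "TrialRecord", "SyncedTimeline",
    "WINDOW_BEFORE_MS", "WINDOW_AFTER_MS", "LATE_MARK_MS",
    "synchronize", "detect_toe_contact", "detect_heel_contact",
    "peak_vgrf_bw", "make_trial_events",
]

WINDOW_BEFORE_MS = 33.0
WINDOW_AFTER_MS = 250.0
LATE_MARK_MS = 150.0


@dataclass
class ForcePlateRecord:
    """Vertical ground-reaction-force time series (uniform grid, N, ms)."""

    time_ms: np.ndarray
    fz_n: np.ndarray
    rate_hz: float = 1000.0
    body_weight_n: float = 700.0

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.fz_n = np.asarray(self.fz_n, dtype=float)
        if self.rate_hz <= 0 or self.body_weight_n <= 0:
            raise ContractViolationError("rate and body weight must be positive")
        if self.time_ms.shape != self.fz_n.shape or self.time_ms.ndim != 1:
            raise ContractViolationError("time and Fz must be equal-length 1-D")
        dt = np.diff(self.time_ms)
        if len(dt) and not np.allclose(dt, 1000.0 / self.rate_hz, atol=1e-6):
            raise ContractViolationError("time grid inconsistent with rate")

    def shifted(self, offset_ms: float) -> "ForcePlateRecord":
        return ForcePlateRecord(self.time_ms + offset_ms, self.fz_n.copy(),
                                self.rate_hz, self.body_weight_n)

    def fz_at(self, t_ms) -> np.ndarray:
        """Linear interpolation of Fz at arbitrary times."""
        return np.interp(np.asarray(t_ms, dtype=float),
                         self.time_ms, self.fz_n)


@dataclass(frozen=True)
class TrialEvents:
    """Landing events and analysis window, ms on the common (toe-contact) clock."""

    toe_contact: float
    heel_contact: Optional[float]

    @property
    def window_start(self) -> float:
        return self.toe_contact - WINDOW_BEFORE_MS

    @property
    def window_end(self) -> float:
        return self.toe_contact + WINDOW_AFTER_MS

    @property
    def late_mark(self) -> float:
        return self.toe_contact + LATE_MARK_MS

    def validate_ordering(self) -> None:
        """Forefoot-landing ordering: start < toe < heel < +150 < end."""
        if self.heel_contact is None:
            raise ContractViolationError("heel contact was not detected")
        ok = (self.window_start < self.toe_contact < self.heel_contact
              < self.late_mark < self.window_end)
        if not ok:
            raise ContractViolationError(
                f"event ordering violated: toe={self.toe_contact}, "
                f"heel={self.heel_contact}")


@dataclass
class TrialRecord:
    """One synchronized landing trial of one subject in one condition."""

    subject: str
    condition: str                      # barefoot | shod
    trial_index: int
    angles: dict                        # joint name -> JointAngleSeries
    grf: ForcePlateRecord
    events: TrialEvents

    def __post_init__(self) -> None:
        if self.condition not in ("barefoot", "shod"):
            raise ContractViolationError(f"unknown condition {self.condition!r}")


@dataclass
class SyncedTimeline:
    """Fluoro and GRF streams on a shared clock with t = 0 at toe contact."""

    frame_times_ms: np.ndarray
    grf: ForcePlateRecord
    toe_contact_raw_ms: float           # toe contact on the raw GRF clock

    def grf_at_frames(self) -> np.ndarray:
        return self.grf.fz_at(self.frame_times_ms)


def synchronize(fluoro_timestamps_ms, grf: ForcePlateRecord,
                trigger_offset_ms: float = 0.0,
                toe_threshold_n: float = 10.0,
                hold_ms: float = 20.0) -> SyncedTimeline:
    """Put both streams on a common clock with t = 0 at toe contact.

    ``trigger_offset_ms`` is the lag of the force-plate clock behind the
    fluoroscope clock (GRF time + offset = fluoro time).
    """
    ft = np.asarray(fluoro_timestamps_ms, dtype=float)
    grf_on_fluoro = grf.shifted(trigger_offset_ms)
    if grf_on_fluoro.time_ms[-1] < ft[0] or grf_on_fluoro.time_ms[0] > ft[-1]:
        raise SynchronizationError("fluoro and GRF streams do not overlap")
    tc = detect_toe_contact(grf_on_fluoro, threshold_n=toe_threshold_n,
                            hold_ms=hold_ms)
    return SyncedTimeline(frame_times_ms=ft - tc,
                          grf=grf_on_fluoro.shifted(-tc),
                          toe_contact_raw_ms=tc - trigger_offset_ms)


def detect_toe_contact(grf: ForcePlateRecord, threshold_n: float = 10.0,
                       hold_ms: float = 20.0) -> float:
    """First sustained rise of Fz above ``threshold_n``.

    The force must stay above threshold for ``hold_ms`` (rejects brief
    spikes); the returned time is the linear back-interpolation of the
    threshold crossing.
    """
    fz, t = grf.fz_n, grf.time_ms
    if fz[0] > threshold_n:
        raise ContractViolationError("Fz must start below the contact threshold")
    hold_n = max(1, int(round(hold_ms * grf.rate_hz / 1000.0)))
    above = fz > threshold_n
    # first index where `above` holds for hold_n consecutive samples
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= hold_n:
            j = i - run + 1               # first sample of the sustained run
            if j == 0:
                return float(t[0])
            f0, f1 = fz[j - 1], fz[j]
            frac = (threshold_n - f0) / (f1 - f0) if f1 != f0 else 1.0
            return float(t[j - 1] + frac * (t[j] - t[j - 1]))
    raise NoContactError("Fz never rises above the contact threshold")


def detect_heel_contact(calc_poses: Sequence[Optional[RigidPose]],
                        calc_mesh: TriMesh,
                        frame_times_ms,
                        plate_point=(0.0, 0.0, 0.0),
                        plate_normal=(0.0, 1.0, 0.0),
                        height_threshold_mm: float = 5.0,
                        after_ms: float = 0.0) -> Optional[float]:
    """Heel contact: the first time after toe contact when the inferior-most
    calcaneal vertex descends below ``height_threshold_mm`` above the plate.

    Heights are evaluated at the fluoroscopic frame times and the crossing is
    linearly interpolated between frames.  Returns ``None`` when the heel
    never descends below threshold inside the window (toe-standing trial).
    """
    t = np.asarray(frame_times_ms, dtype=float)
    n_hat = np.asarray(plate_normal, dtype=float)
    n_hat = n_hat / np.linalg.norm(n_hat)
    p0 = np.asarray(plate_point, dtype=float)
    heights = np.full(len(t), np.nan)
    for k, pose in enumerate(calc_poses):
        if pose is None:
            continue
        v = pose.apply(calc_mesh.vertices)
        heights[k] = np.min((v - p0) @ n_hat)
    ok = ~np.isnan(heights)
    for k in range(1, len(t)):
        if t[k] < after_ms or not (ok[k] and ok[k - 1]):
            continue
        if heights[k] <= height_threshold_mm < heights[k - 1]:
            h0, h1 = heights[k - 1], heights[k]
            frac = (h0 - height_threshold_mm) / (h0 - h1)
            return float(t[k - 1] + frac * (t[k] - t[k - 1]))
        if heights[k] <= height_threshold_mm and t[k - 1] < after_ms <= t[k]:
            return float(t[k])
    return None


def peak_vgrf_bw(grf: ForcePlateRecord, window_ms=None) -> float:
    """Maximum vertical GRF in the window, as a multiple of body weight."""
    fz, t = grf.fz_n, grf.time_ms
    if window_ms is not None:
        lo, hi = window_ms
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            raise ContractViolationError("empty GRF window")
        fz = fz[mask]
    return float(fz.max() / grf.body_weight_n)


def make_trial_events(grf: ForcePlateRecord,
                      calc_poses: Sequence[Optional[RigidPose]],
                      calc_mesh: TriMesh, frame_times_ms,
                      toe_threshold_n: float = 10.0, hold_ms: float = 20.0,
                      height_threshold_mm: float = 5.0,
                      plate_point=(0.0, 0.0, 0.0),
                      plate_normal=(0.0, 1.0, 0.0)) -> TrialEvents:
    """Detect both events on an already-synchronized trial (t = 0 at toe
    contact on the supplied clocks)."""
    tc = detect_toe_contact(grf, threshold_n=toe_threshold_n, hold_ms=hold_ms)
    hc = detect_heel_contact(calc_poses, calc_mesh, frame_times_ms,
                             plate_point=plate_point, plate_normal=plate_normal,
                             height_threshold_mm=height_threshold_mm,
                             after_ms=tc)
    return TrialEvents(toe_contact=tc, heel_contact=hc)
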