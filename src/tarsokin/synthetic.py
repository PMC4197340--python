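"""Synthetic phantom data with known ground truth.

Everything the pipeline consumes can be generated here: parametric phantom
bones (distal tibia, talus, calcaneus) with analytically placed landmarks,
scripted forefoot-landing motions whose joint-angle curves are closed-form
(PCHIP through study-shaped control points), cone-beam silhouette renders
of the landing at 60 Hz, and impact-peaked vertical GRF traces at 1000 Hz.

The default motion scripts and cohort parameters are seeded from the
published condition summaries of a seven-subject barefoot-vs-shod forefoot
landing experiment: toe-contact angles (e.g. talocrural plantarflexion
−20.5° barefoot / −17.9° shod), per-period angular changes, peak vertical
GRF (1.58 / 1.39 body weights) and their SDs and paired p-values, so that
synthetic cohorts are study-shaped in means, spread and significance
structure.  The phantoms are geometric primitives, not anatomical shapes:
the talar trochlea is an analytic cylindrical band (radius ~19 mm) so the
circle fit has a closed-form truth, and the calcaneus is a wedge whose
inferior surface is horizontal at neutral stance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import trimesh as _tm
from scipy import stats as sps
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import gaussian_filter

from .anatomy import (AnatomicalFrame, LandmarkSet, TriMesh, build_frame)
from .errors import ContractViolationError, ProjectionError
from .events import (ForcePlateRecord, TrialEvents, TrialRecord,
                     detect_heel_contact, detect_toe_contact)
from .kinematics import (AXES, JointAngleSeries, SUBTALAR, TALOCRURAL,
                         jcs_compose)
from .registration import CameraModel, FluoroSequence, render_coverage
from .rigid import RigidPose

__all__ = [
    "PhantomSpec", "Phantom", "MotionScript", "CohortSpec", "SyntheticTrial",
    "VariableSummary", "STUDY_SUMMARY", "JOINTS",
    "make_phantom", "default_camera", "condition_script", "make_trial",
    "make_cohort", "static_reference_poses",
]

JOINTS = {"talocrural": TALOCRURAL, "subtalar": SUBTALAR}


# ---------------------------------------------------------------------------
# study-shaped condition summaries (generator defaults)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSummary:
    """Published condition summary for one outcome variable."""

    mean_barefoot: float
    sd_barefoot: float
    mean_shod: float
    sd_shod: float
    p: float

    @property
    def mean_difference(self) -> float:
        return self.mean_barefoot - self.mean_shod

    def implied_diff_sd(self, n: int = 7) -> float:
        """Paired-difference SD implied by the two-tailed p at n subjects."""
        t_obs = sps.t.ppf(1.0 - self.p / 2.0, n - 1)
        return abs(self.mean_difference) * math.sqrt(n) / t_obs


# keys follow stats.trial_variables: tc|joint|axis, period|joint|axis
STUDY_SUMMARY: Dict[str, VariableSummary] = {
    # toe-contact angles
    "tc|talocrural|dorsiflexion":      VariableSummary(-20.5, 7.1, -17.9, 8.3, 0.008),
    "tc|talocrural|eversion":          VariableSummary(0.1, 1.6, -1.4, 2.0, 0.071),
    "tc|talocrural|external_rotation": VariableSummary(0.8, 1.3, 1.7, 1.3, 0.393),
    "tc|subtalar|dorsiflexion":        VariableSummary(-3.0, 2.3, -2.3, 1.7, 0.231),
    "tc|subtalar|eversion":            VariableSummary(-4.7, 1.5, -4.1, 2.3, 0.111),
    "tc|subtalar|external_rotation":   VariableSummary(-2.2, 2.2, -1.9, 3.1, 0.471),
    # toe contact -> heel contact changes
    "toe_contact_to_heel_contact|talocrural|dorsiflexion":      VariableSummary(9.8, 9.2, 9.0, 5.0, 0.763),
    "toe_contact_to_heel_contact|talocrural|eversion":          VariableSummary(-0.9, 1.0, 2.1, 1.7, 0.076),
    "toe_contact_to_heel_contact|talocrural|external_rotation": VariableSummary(-1.5, 1.2, -2.6, 2.1, 0.083),
    "toe_contact_to_heel_contact|subtalar|dorsiflexion":        VariableSummary(2.0, 1.4, 1.7, 1.3, 0.494),
    "toe_contact_to_heel_contact|subtalar|eversion":            VariableSummary(1.8, 1.0, 3.0, 0.9, 0.083),
    "toe_contact_to_heel_contact|subtalar|external_rotation":   VariableSummary(2.1, 0.9, 3.5, 1.8, 0.197),
    # heel contact -> 150 ms changes
    "heel_contact_to_150ms|talocrural|dorsiflexion":      VariableSummary(10.0, 1.9, 10.8, 3.1, 0.431),
    "heel_contact_to_150ms|talocrural|eversion":          VariableSummary(1.4, 0.7, 1.7, 1.4, 0.412),
    "heel_contact_to_150ms|talocrural|external_rotation": VariableSummary(-2.2, 1.9, 2.4, 1.4, 0.664),
    "heel_contact_to_150ms|subtalar|dorsiflexion":        VariableSummary(2.2, 2.1, 0.7, 0.4, 0.074),
    "heel_contact_to_150ms|subtalar|eversion":            VariableSummary(3.2, 2.3, 0.7, 0.7, 0.044),
    "heel_contact_to_150ms|subtalar|external_rotation":   VariableSummary(2.5, 2.2, 2.1, 2.2, 0.769),
    # peak vertical GRF per body weight
    "peak_vgrf_bw": VariableSummary(1.58, 0.58, 1.39, 0.54, 0.031),
}


# ---------------------------------------------------------------------------
# phantom bones
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Shape parameters (mm) of the parametric phantom bones."""

    tibia_shaft_length: float = 50.0
    tibia_radius: float = 14.0
    talus_radius: float = 19.0          # trochlear (circle-fit) radius
    talus_width: float = 28.0
    calc_length: float = 60.0
    calc_width: float = 28.0
    calc_height: float = 38.0
    calc_incline_deg: float = 20.0      # inferior-surface pitch in model coords
    sections: int = 24                  # cylinder tessellation
    jitter_mm: float = 0.02             # seeded vertex jitter
    seed: int = 0

    def __post_init__(self) -> None:
        dims = (self.tibia_shaft_length, self.tibia_radius, self.talus_radius,
                self.talus_width, self.calc_length, self.calc_width,
                self.calc_height)
        if any(d <= 0 for d in dims):
            raise ContractViolationError("phantom dimensions must be positive")
        if self.sections < 12:
            raise ContractViolationError(
                "tessellation too coarse to carry the landmark set")


@dataclass
class Phantom:
    meshes: Dict[str, TriMesh]
    landmarks: Dict[str, LandmarkSet]
    frames: Dict[str, AnatomicalFrame]
    spec: PhantomSpec


def _jitter(mesh: _tm.Trimesh, sigma: float, rng: np.random.Generator) -> np.ndarray:
    v = mesh.vertices.copy()
    if sigma > 0:
        v = v + rng.normal(0.0, sigma, v.shape)
    return v


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> Phantom:
    """Three articulating phantom bones with analytic landmarks.

    Model coordinates are anatomical-ish per bone: X anterior, Y proximal,
    Z lateral (right foot).  The talar trochlea is the upper surface of a
    cylinder about the Z axis, so its circumscribing circle has the exact
    centre (0, 0, 0) and radius ``talus_radius``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec
    meshes: Dict[str, TriMesh] = {}
    landmarks: Dict[str, LandmarkSet] = {}

    # --- tibia: shaft cylinder along Y, distal plafond face at y = 0,
    #     plus a medial-malleolus block that breaks the axial symmetry
    #     (a plain cylinder's silhouette cannot constrain shaft rotation) --
    cyl = _tm.creation.cylinder(radius=s.tibia_radius,
                                height=s.tibia_shaft_length,
                                sections=s.sections)
    rot = _tm.transformations.rotation_matrix(-np.pi / 2, [1, 0, 0])
    cyl.apply_transform(rot)            # z axis -> y axis
    cyl.apply_translation([0, s.tibia_shaft_length / 2, 0])
    mall = _tm.creation.box(extents=(9.0, 20.0, 7.0))
    mall.apply_translation([0.0, 0.0, -(s.talus_width / 2 + 4.5)])
    tib = _tm.util.concatenate([cyl, mall])
    n_cyl = len(cyl.vertices)
    meshes["tibia"] = TriMesh(
        _jitter(tib, s.jitter_mm, rng), tib.faces, "tibia",
        convex_components=[np.arange(n_cyl),
                           np.arange(n_cyl, len(tib.vertices))])
    ring = np.linspace(0, 2 * np.pi, 12, endpoint=False)
    plafond = np.c_[s.tibia_radius * np.cos(ring),
                    np.zeros(12),
                    s.tibia_radius * np.sin(ring)]
    a = math.radians(20.0)
    landmarks["tibia"] = LandmarkSet("tibia", {
        "plafond_boundary": plafond,
        "shaft_point": [0.0, s.tibia_shaft_length, 0.0],
        "anteromedial_edge": [s.tibia_radius * math.cos(a), 0.0,
                              -s.tibia_radius * math.sin(a)],
        "anterolateral_edge": [s.tibia_radius * math.cos(a), 0.0,
                               s.tibia_radius * math.sin(a)],
    })

    # --- talus: trochlear arc band about Z (the analytic cylinder the
    #     circle fit recovers) over a flat body with an anterior neck;
    #     the flat bottom and neck make trochlear rotation visible in the
    #     silhouette ------------------------------------------------------
    R, W = s.talus_radius, s.talus_width
    arc_angles = np.radians(np.arange(30.0, 150.1, 7.5))
    pts = []
    for z in (-W / 2, 0.0, W / 2):
        pts += [[R * math.cos(t), R * math.sin(t), z] for t in arc_angles]
    for z in (-W * 0.45, W * 0.45):
        pts += [[-0.72 * R, -0.5 * R, z], [0.72 * R, -0.5 * R, z],
                [1.35 * R, 0.1 * R, 0.6 * z]]          # anterior neck
    tal = _tm.convex.convex_hull(np.asarray(pts))
    meshes["talus"] = TriMesh(_jitter(tal, s.jitter_mm, rng), tal.faces,
                              "talus",
                              convex_components=[np.arange(len(tal.vertices))])
    c45 = math.cos(math.radians(45.0))
    arc = np.radians(np.linspace(55.0, 125.0, 7))
    landmarks["talus"] = LandmarkSet("talus", {
        "trochlear_surface": np.c_[R * np.cos(arc), R * np.sin(arc),
                                   np.zeros(len(arc))],
        "anteromedial_edge": [R * c45, R * c45, -W / 2],
        "anterolateral_edge": [R * c45, R * c45, W / 2],
        "posteromedial_edge": [-R * c45, R * c45, -W / 2],
        "posterolateral_edge": [-R * c45, R * c45, W / 2],
        "anterior_edge": [R * c45, R * c45, 0.0],
        "posterior_edge": [-R * c45, R * c45, 0.0],
    })

    # --- calcaneus: wedge, inferior surface inclined by calc_incline ------
    L, Wc, H = s.calc_length, s.calc_width, s.calc_height
    x_post, x_ant = -7 * L / 12, 5 * L / 12
    tan_i = math.tan(math.radians(s.calc_incline_deg))
    y_ant = (x_ant - x_post) * tan_i
    corners = []
    for z in (-Wc / 2, Wc / 2):
        corners += [[x_post, 0.0, z], [x_ant, y_ant, z],
                    [x_post, H, z], [x_ant, H, z]]
    hull = _tm.convex.convex_hull(np.array(corners))
    # sustentaculum-tali-like medial process poking above the dorsal outline:
    # a z-symmetric box silhouette is first-order invariant to tilt about the
    # anterior axis (compensated by depth), which would leave the eversion
    # axis untracked; an off-midline outline feature restores observability
    sus = _tm.creation.box(extents=(16.0, 9.0, 9.0))
    sus.apply_translation([L / 8, H + 2.0, -(Wc / 2 + 5.5)])
    cal = _tm.util.concatenate([hull, sus])
    n_hull = len(hull.vertices)
    meshes["calcaneus"] = TriMesh(
        _jitter(cal, s.jitter_mm, rng), cal.faces, "calcaneus",
        convex_components=[np.arange(n_hull),
                           np.arange(n_hull, len(cal.vertices))])
    xs = np.linspace(x_post + 5, x_ant - 5, 4)
    inferior = np.c_[xs, (xs - x_post) * tan_i, np.full(4, 0.0)]
    inferior[:, 2] = [-Wc / 4, Wc / 4, -Wc / 4, Wc / 4]
    lateral = np.array([[x_post + 10, H / 2, Wc / 2],
                        [x_ant - 10, H / 2 + 8, Wc / 2],
                        [x_post + 15, H - 6, Wc / 2],
                        [x_ant - 20, H - 10, Wc / 2]])
    landmarks["calcaneus"] = LandmarkSet("calcaneus", {
        "posterior_lateral_articular": [-L / 12, H, Wc / 2],
        "middle_medial_articular": [L / 4, H, -Wc / 2],
        "inferior_surface": inferior,
        "lateral_surface": lateral,
        "anterior_point": [x_ant, H - 8, 0.0],
    })

    frames = {b: build_frame(meshes[b], landmarks[b]) for b in meshes}
    return Phantom(meshes=meshes, landmarks=landmarks, frames=frames, spec=s)


def default_camera() -> CameraModel:
    """Lateral-view cone-beam geometry framing the landing volume."""
    return CameraModel(source_position=(0.0, 80.0, 0.0),
                       detector_distance=1000.0, pixel_pitch=1.2,
                       principal_point=(128.0, 128.0), image_size=(256, 256))


# ---------------------------------------------------------------------------
# motion scripts
# ---------------------------------------------------------------------------

FRAME_RATE_HZ = 60.0
FRAME_PERIOD_MS = 1000.0 / FRAME_RATE_HZ
GRF_RATE_HZ = 1000.0
SCENE_DEPTH_MM = 700.0
TALOCRURAL_OFFSET = (0.0, -21.0, 0.0)   # talus origin in tibial anat coords
SUBTALAR_OFFSET = (0.0, -21.0, 0.0)     # calcaneus origin in talar anat coords


@dataclass(frozen=True)
class MotionScript:
    """Closed-form description of one landing: per-joint angle curves
    (PCHIP through control points at −60, 0, heel-contact, 150 and 300 ms),
    the global descent trajectory, and the GRF shape parameters.

    Angle values are JCS degrees relative to the static standing reference;
    times are ms relative to toe contact.
    """

    condition: str = "barefoot"
    tc_angles: Dict[str, float] = field(default_factory=dict)   # joint|axis -> deg
    d1: Dict[str, float] = field(default_factory=dict)          # tc -> hc change
    d2: Dict[str, float] = field(default_factory=dict)          # hc -> 150 change
    heel_time_ms: float = 80.0
    peak_vgrf_bw: float = 1.58
    body_weight_n: float = 700.0
    drop_height_mm: float = 100.0        # platform drop (sets impact velocity)
    forward_drift_mm: float = 15.0       # of the 40 cm forward hop, the part
                                         # crossing the fluoroscopic field
    settle_mm: float = 18.0
    settle_duration_ms: float = 150.0
    toe_clearance_mm: float = 14.0       # calc lowest vertex height at t=0
    tail_frac: float = 0.25
    grf_peak_time_ms: float = 45.0
    grf_ramp_ms: float = 25.0

    @property
    def impact_velocity_mm_ms(self) -> float:
        return math.sqrt(2.0 * 9.81e-3 * self.drop_height_mm)  # mm/ms

    def angle_curve(self, joint: str, axis: str) -> PchipInterpolator:
        key = f"{joint}|{axis}"
        v0 = self.tc_angles[key]
        d1, d2 = self.d1[key], self.d2[key]
        t = [-60.0, 0.0, self.heel_time_ms, 150.0, 300.0]
        v = [v0, v0, v0 + d1, v0 + d1 + d2, v0 + d1 + d2 + self.tail_frac * d2]
        return PchipInterpolator(t, v)

    def angles_at(self, t_ms, joint: str) -> np.ndarray:
        """(n, 3) JCS angles (dorsi, ever, ext) at the given times."""
        t = np.atleast_1d(np.asarray(t_ms, dtype=float))
        return np.stack([self.angle_curve(joint, ax)(t) for ax in AXES], axis=1)

    def descent_mm(self, t_ms: float) -> float:
        """Vertical offset of the shank relative to its final stance height.

        Free fall before toe contact, then a smoothstep sink of
        ``settle_mm`` over ``settle_duration_ms`` (the forefoot strike
        arrests the fall; the body keeps lowering onto the heel)."""
        if t_ms < 0:
            return self.impact_velocity_mm_ms * (-t_ms) + self.settle_mm
        u = min(t_ms / self.settle_duration_ms, 1.0)
        return self.settle_mm * (1.0 - (3.0 * u * u - 2.0 * u ** 3))

    def forward_mm(self, t_ms: float) -> float:
        u = np.clip((t_ms + 33.0) / 183.0, 0.0, 1.0)
        return self.forward_drift_mm * float(u)


def condition_script(condition: str, overrides: Optional[Dict[str, float]] = None,
                     **kwargs) -> MotionScript:
    """Motion script whose defaults are the published condition summaries.

    ``overrides`` replaces individual variable values (same keys as
    :data:`STUDY_SUMMARY`), e.g. for subject-level random effects.
    """
    if condition not in ("barefoot", "shod"):
        raise ContractViolationError(f"unknown condition {condition!r}")
    values = {k: (v.mean_barefoot if condition == "barefoot" else v.mean_shod)
              for k, v in STUDY_SUMMARY.items()}
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise ContractViolationError(f"unknown override keys {sorted(unknown)}")
        values.update(overrides)
    tc, d1, d2 = {}, {}, {}
    for joint in JOINTS:
        for ax in AXES:
            key = f"{joint}|{ax}"
            tc[key] = values[f"tc|{key}"]
            d1[key] = values[f"toe_contact_to_heel_contact|{key}"]
            d2[key] = values[f"heel_contact_to_150ms|{key}"]
    return MotionScript(condition=condition, tc_angles=tc, d1=d1, d2=d2,
                        peak_vgrf_bw=values["peak_vgrf_bw"], **kwargs)


# ---------------------------------------------------------------------------
# scene assembly
# ---------------------------------------------------------------------------

class _Scene:
    """Poses of the three bones under a script, with the vertical offset
    solved so the calcaneus clears the plate by ``toe_clearance_mm`` at
    toe contact (the unmodelled forefoot is what actually touches)."""

    def __init__(self, phantom: Phantom, script: MotionScript):
        self.phantom = phantom
        self.script = script
        self.y_offset = 0.0
        h0 = self._calc_min_height(0.0)
        self.y_offset = script.toe_clearance_mm - h0

    def tibia_anat(self, t: float) -> RigidPose:
        s = self.script
        pos = np.array([s.forward_mm(t), self.y_offset + s.descent_mm(t),
                        SCENE_DEPTH_MM])
        return RigidPose(np.eye(3), pos, _skip_check=True)

    def poses_at(self, t: float) -> Dict[str, RigidPose]:
        s = self.script
        frames = self.phantom.frames
        a_tib = self.tibia_anat(t)
        rel_tc = jcs_compose(*s.angles_at(t, "talocrural")[0],
                             translation=TALOCRURAL_OFFSET)
        a_tal = a_tib @ rel_tc
        rel_st = jcs_compose(*s.angles_at(t, "subtalar")[0],
                             translation=SUBTALAR_OFFSET)
        a_cal = a_tal @ rel_st
        return {"tibia": a_tib @ frames["tibia"].to_pose(),
                "talus": a_tal @ frames["talus"].to_pose(),
                "calcaneus": a_cal @ frames["calcaneus"].to_pose()}

    def _calc_min_height(self, t: float) -> float:
        pose = self.poses_at(t)["calcaneus"]
        return float(pose.apply(self.phantom.meshes["calcaneus"].vertices)[:, 1].min())

    def heel_contact_truth(self, threshold_mm: float = 5.0,
                           t_max: float = 250.0, dt: float = 1.0) -> Optional[float]:
        """Heel-contact time from the scripted motion at fine sampling,
        using the same inferior-vertex rule as the detector."""
        prev_t, prev_h = 0.0, self._calc_min_height(0.0)
        for t in np.arange(dt, t_max + dt / 2, dt):
            h = self._calc_min_height(float(t))
            if h <= threshold_mm < prev_h:
                frac = (prev_h - threshold_mm) / (prev_h - h)
                return float(prev_t + frac * (t - prev_t))
            prev_t, prev_h = float(t), h
        return None


def static_reference_poses(phantom: Phantom,
                           stance_clearance_mm: float = 0.5
                           ) -> Dict[str, RigidPose]:
    """Standing reference: both joints at JCS (0, 0, 0), foot flat on the
    plate (calcaneus inferior surface ``stance_clearance_mm`` above it)."""
    script = condition_script("barefoot")
    neutral = replace(script,
                      tc_angles={k: 0.0 for k in script.tc_angles},
                      d1={k: 0.0 for k in script.d1},
                      d2={k: 0.0 for k in script.d2},
                      settle_mm=0.0, forward_drift_mm=0.0,
                      toe_clearance_mm=stance_clearance_mm)
    return _Scene(phantom, neutral).poses_at(0.0)


# ---------------------------------------------------------------------------
# trial generation
# ---------------------------------------------------------------------------

def frame_grid(n_before: int = 2, n_after: int = 15) -> np.ndarray:
    """60 Hz frame times (ms), toe contact on frame 0: −33.3 ... +250."""
    return np.arange(-n_before, n_after + 1) * FRAME_PERIOD_MS


@dataclass
class SyntheticTrial:
    """A generated landing with its full ground-truth bundle."""

    condition: str
    camera: CameraModel
    sequence: Optional[FluoroSequence]
    grf: ForcePlateRecord
    frame_times_ms: np.ndarray
    truth_poses: Dict[str, List[RigidPose]]
    truth_angles: Dict[str, JointAngleSeries]
    events: TrialEvents
    script: MotionScript
    phantom: Phantom


def grf_trace(script: MotionScript, rng: Optional[np.random.Generator] = None,
              noise_n: float = 0.0, t_start_ms: float = -100.0,
              t_end_ms: float = 400.0) -> ForcePlateRecord:
    """Impact-peaked vertical GRF: zero before toe contact, ramped impact
    transient peaking at ``peak_vgrf_bw`` body weights, settling to 1 BW."""
    s = script
    t = np.arange(t_start_ms, t_end_ms + 0.5, 1000.0 / GRF_RATE_HZ)
    bw = s.body_weight_n
    g = (t / s.grf_peak_time_ms) * np.exp(1.0 - t / s.grf_peak_time_ms)
    ramp = np.clip(t / s.grf_ramp_ms, 0.0, 1.0)
    fz = np.where(t >= 0.0, bw * ramp * (1.0 + (s.peak_vgrf_bw - 1.0) * g), 0.0)
    if noise_n > 0 and rng is not None:
        fz = fz + rng.normal(0.0, noise_n, fz.shape)
    return ForcePlateRecord(time_ms=t, fz_n=fz, rate_hz=GRF_RATE_HZ,
                            body_weight_n=bw)


def render_scene_frame(camera: CameraModel, phantom: Phantom,
                       poses: Dict[str, RigidPose],
                       rng: Optional[np.random.Generator] = None,
                       noise_sigma: float = 0.02, blur_px: float = 1.0,
                       absorption: float = 0.45) -> np.ndarray:
    """Additive-attenuation silhouette render of the three bones."""
    h = camera.image_size[1]
    img = np.full((h, camera.image_size[0]), 0.95)
    for bone, mesh in phantom.meshes.items():
        img -= absorption * render_coverage(camera, mesh, poses[bone])
    img = np.clip(img, 0.03, 1.0)
    if blur_px > 0:
        img = gaussian_filter(img, blur_px)
    if noise_sigma > 0 and rng is not None:
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    return np.clip(img, 0.0, 1.0)


def make_trial(phantom: Phantom, script: MotionScript,
               camera: Optional[CameraModel] = None, seed: int = 0,
               render: bool = True, image_noise: float = 0.02,
               blur_px: float = 1.0, grf_noise_n: float = 3.0,
               n_before: int = 2, n_after: int = 15) -> SyntheticTrial:
    """Generate one landing trial with its ground truth.

    Poses are sampled at 60 Hz from the script through the forward JCS map;
    images (when ``render``) are silhouette renders with seeded blur and
    Gaussian noise; the GRF is the scripted impact trace plus noise.  The
    ground-truth bundle carries the exact poses, the script's angle curves
    sampled on the frame grid, and events (toe contact at 0 by
    construction; heel contact from the scripted geometry at 1 ms sampling).
    """
    camera = camera or default_camera()
    rng = np.random.default_rng(seed)
    times = frame_grid(n_before, n_after)
    scene = _Scene(phantom, script)
    truth_poses = {b: [] for b in phantom.meshes}
    images = []
    for t in times:
        poses = scene.poses_at(float(t))
        for b in truth_poses:
            truth_poses[b].append(poses[b])
        if render:
            try:
                images.append(render_scene_frame(
                    camera, phantom, poses, rng,
                    noise_sigma=image_noise, blur_px=blur_px))
            except ProjectionError as exc:
                raise ProjectionError(
                    f"frame at t={t:.1f} ms leaves the viewing frustum: {exc}"
                ) from exc
    sequence = None
    if render:
        sequence = FluoroSequence(frames=images, timestamps_ms=times,
                                  rate_hz=FRAME_RATE_HZ)
    grf = grf_trace(script, rng, noise_n=grf_noise_n)
    truth_angles = {
        joint: JointAngleSeries(
            joint=joint, time_ms=times,
            **dict(zip(AXES, script.angles_at(times, joint).T)))
        for joint in JOINTS}
    events = TrialEvents(toe_contact=0.0,
                         heel_contact=scene.heel_contact_truth())
    return SyntheticTrial(condition=script.condition, camera=camera,
                          sequence=sequence, grf=grf, frame_times_ms=times,
                          truth_poses=truth_poses, truth_angles=truth_angles,
                          events=events, script=script, phantom=phantom)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """A paired-design synthetic cohort (each subject in both conditions)."""

    n_subjects: int = 7
    n_trials: int = 3
    angle_noise_deg: float = 0.25    # per-frame measurement noise on angles
    grf_noise_n: float = 3.0
    between_subject_scale: float = 1.0   # scales the study-SD random effects
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials < 1:
            raise ContractViolationError("need ≥1 subject and ≥1 trial")


def _draw_subject_effects(rng: np.random.Generator, spec: CohortSpec
                          ) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Per-variable (barefoot, shod) values for one subject.

    value_b = mean_b + a + e/2, value_s = mean_s + a − e/2 with the shared
    effect a ~ N(0, σ_a) and the paired difference e ~ N(0, σ_d); σ_d is
    implied by the published p-value, σ_a chosen so the marginal SD matches
    the published condition SD.
    """
    vb, vs = {}, {}
    for key, summ in STUDY_SUMMARY.items():
        # the paired-difference SD can never exceed the sum of the two
        # condition SDs; the cap guards against internally inconsistent
        # published rows (large printed difference with a large p)
        sd_d = (min(summ.implied_diff_sd(),
                    summ.sd_barefoot + summ.sd_shod)
                * spec.between_subject_scale)
        sd_marg = 0.5 * (summ.sd_barefoot + summ.sd_shod) * spec.between_subject_scale
        sd_a = math.sqrt(max(sd_marg ** 2 - sd_d ** 2 / 4.0, 0.0))
        a = rng.normal(0.0, sd_a)
        e = rng.normal(0.0, sd_d)
        vb[key] = summ.mean_barefoot + a + e / 2.0
        vs[key] = summ.mean_shod + a - e / 2.0
    return vb, vs


def _overrides_to_script(condition: str, values: Dict[str, float]) -> MotionScript:
    over = {k: v for k, v in values.items() if k != "peak_vgrf_bw"}
    # keep the GRF physically plausible for a landing
    peak = max(values["peak_vgrf_bw"], 1.05)
    return replace(condition_script(condition, overrides=over),
                   peak_vgrf_bw=peak)


def make_cohort(spec: CohortSpec = CohortSpec(),
                phantom: Optional[Phantom] = None,
                detect_heel: bool = True):
    """Paired-condition trial records for a synthetic cohort.

    Angle series are the scripted curves sampled on the 60 Hz grid plus
    seeded measurement noise (no rendering/registration — the cohort layer
    stands in for the study's processed per-trial outcomes); heel contact
    comes from the scripted calcaneus geometry.  Returns ``(trials,
    effects)`` where ``effects`` is the per-subject ground-truth table.
    """
    rng = np.random.default_rng(spec.seed)
    phantom = phantom or make_phantom()
    times = frame_grid()
    trials: List[TrialRecord] = []
    effect_rows = []
    for si in range(spec.n_subjects):
        subject = f"S{si + 1:02d}"
        vb, vs = _draw_subject_effects(rng, spec)
        effect_rows.extend(
            {"subject": subject, "variable": k,
             "barefoot_true": vb[k], "shod_true": vs[k],
             "true_difference": vb[k] - vs[k]} for k in vb)
        for condition, values in (("barefoot", vb), ("shod", vs)):
            script = _overrides_to_script(condition, values)
            if detect_heel:
                scene = _Scene(phantom, script)
                calc_poses = [scene.poses_at(float(t))["calcaneus"]
                              for t in times]
            for ti in range(spec.n_trials):
                angles = {}
                for joint in JOINTS:
                    vals = script.angles_at(times, joint)
                    vals = vals + rng.normal(0.0, spec.angle_noise_deg, vals.shape)
                    angles[joint] = JointAngleSeries(
                        joint=joint, time_ms=times,
                        **dict(zip(AXES, vals.T)))
                grf = grf_trace(script, rng, noise_n=spec.grf_noise_n)
                tc = detect_toe_contact(grf)
                hc_det = (detect_heel_contact(calc_poses,
                                              phantom.meshes["calcaneus"],
                                              times, after_ms=tc)
                          if detect_heel else None)
                trials.append(TrialRecord(
                    subject=subject, condition=condition, trial_index=ti,
                    angles=angles, grf=grf,
                    events=TrialEvents(toe_contact=tc, heel_contact=hc_det)))
    return trials, pd.DataFrame(effect_rows)
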