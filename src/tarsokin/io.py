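"""Readers and writers for the pipeline's on-disk formats.

Meshes are STL (ASCII or binary) or PLY; landmarks are JSON
``{bone: {label: [x, y, z] | [[x, y, z], ...]}}`` in mm model coordinates;
camera geometry is YAML; GRF traces are CSV with a YAML sidecar; poses,
angle series and summary tables are CSV; events and manifests are JSON.
Units everywhere: mm, ms, degrees, newtons.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import trimesh as _tm
import yaml
from PIL import Image

from .anatomy import AnatomicalFrame, LandmarkSet, TriMesh
from .errors import MeshParseError
from .events import ForcePlateRecord, TrialEvents
from .kinematics import JointAngleSeries
from .registration import CameraModel, FluoroSequence, RegistrationResult
from .rigid import RigidPose

__all__ = [
    "read_mesh", "write_mesh", "read_landmarks", "write_landmarks",
    "read_camera", "write_camera", "read_grf", "write_grf",
    "write_poses", "read_poses", "write_angle_series", "read_angle_series",
    "write_events", "read_events", "write_frames", "read_frames",
    "write_trial_dir", "read_trial_dir",
]


# -- meshes -----------------------------------------------------------------

def read_mesh(path, name: str = "") -> TriMesh:
    """Load an STL or PLY surface into a :class:`TriMesh`."""
    path = Path(path)
    try:
        m = _tm.load_mesh(str(path), process=False)
    except Exception as exc:                       # noqa: BLE001
        raise MeshParseError(f"cannot parse mesh {path}: {exc}") from exc
    if not hasattr(m, "vertices") or len(getattr(m, "vertices", [])) == 0:
        raise MeshParseError(f"no geometry parsed from {path}")
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces),
                   name or path.stem)


def write_mesh(mesh: TriMesh, path, ascii_stl: bool = False) -> None:
    path = Path(path)
    m = _tm.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    if path.suffix.lower() == ".stl" and ascii_stl:
        path.write_text(m.export(file_type="stl_ascii"))
    else:
        m.export(str(path))


# -- landmarks --------------------------------------------------------------

def write_landmarks(landmarks: Dict[str, LandmarkSet], path) -> None:
    payload = {bone: {label: np.asarray(p).tolist()
                      for label, p in lm.points.items()}
               for bone, lm in landmarks.items()}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_landmarks(path) -> Dict[str, LandmarkSet]:
    payload = json.loads(Path(path).read_text())
    return {bone: LandmarkSet(bone, {k: np.asarray(v) for k, v in d.items()})
            for bone, d in payload.items()}


# -- camera -----------------------------------------------------------------

def write_camera(camera: CameraModel, path) -> None:
    Path(path).write_text(yaml.safe_dump({
        "source_position": list(camera.source_position),
        "detector_distance": camera.detector_distance,
        "pixel_pitch": camera.pixel_pitch,
        "principal_point": list(camera.principal_point),
        "image_size": list(camera.image_size),
    }))


def read_camera(path) -> CameraModel:
    d = yaml.safe_load(Path(path).read_text())
    return CameraModel(source_position=tuple(d["source_position"]),
                       detector_distance=float(d["detector_distance"]),
                       pixel_pitch=float(d["pixel_pitch"]),
                       principal_point=tuple(d["principal_point"]),
                       image_size=tuple(int(v) for v in d["image_size"]))


# -- GRF --------------------------------------------------------------------

def write_grf(grf: ForcePlateRecord, csv_path, sidecar_path=None) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_ms": grf.time_ms, "fz_n": grf.fz_n}).to_csv(
        csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
    sidecar.write_text(yaml.safe_dump({"rate_hz": grf.rate_hz,
                                       "body_weight_n": grf.body_weight_n}))


def read_grf(csv_path, sidecar_path=None) -> ForcePlateRecord:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    sidecar = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".yaml")
    meta = yaml.safe_load(sidecar.read_text())
    return ForcePlateRecord(time_ms=df["time_ms"].to_numpy(),
                            fz_n=df["fz_n"].to_numpy(),
                            rate_hz=float(meta["rate_hz"]),
                            body_weight_n=float(meta["body_weight_n"]))


# -- poses ------------------------------------------------------------------

def write_poses(result: RegistrationResult, path) -> None:
    rows = []
    for bone, poses in result.poses.items():
        for k, pose in enumerate(poses):
            if pose is None:
                rows.append({"frame_index": k, "bone": bone,
                             **{c: np.nan for c in
                                ("rx_deg", "ry_deg", "rz_deg",
                                 "tx_mm", "ty_mm", "tz_mm")},
                             "cost": result.costs[bone][k],
                             "converged": False})
                continue
            p = pose.params()
            rows.append({"frame_index": k, "bone": bone,
                         "rx_deg": p[0], "ry_deg": p[1], "rz_deg": p[2],
                         "tx_mm": p[3], "ty_mm": p[4], "tz_mm": p[5],
                         "cost": result.costs[bone][k],
                         "converged": bool(result.converged[bone][k])})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_poses(path) -> RegistrationResult:
    df = pd.read_csv(path)
    poses: Dict[str, List[Optional[RigidPose]]] = {}
    costs, converged = {}, {}
    for bone, sub in df.groupby("bone"):
        sub = sub.sort_values("frame_index")
        ps = []
        for _, r in sub.iterrows():
            if np.isnan(r["rx_deg"]):
                ps.append(None)
            else:
                ps.append(RigidPose.from_euler_deg(
                    [r["rx_deg"], r["ry_deg"], r["rz_deg"]],
                    [r["tx_mm"], r["ty_mm"], r["tz_mm"]]))
        poses[bone] = ps
        costs[bone] = sub["cost"].to_numpy()
        converged[bone] = sub["converged"].to_numpy(dtype=bool)
    return RegistrationResult(poses=poses, costs=costs, converged=converged)


# -- angle series / events --------------------------------------------------

def write_angle_series(series: Dict[str, JointAngleSeries], path) -> None:
    pd.concat([s.to_frame() for s in series.values()]).to_csv(path, index=False)


def read_angle_series(path) -> Dict[str, JointAngleSeries]:
    df = pd.read_csv(path)
    out = {}
    for joint, sub in df.groupby("joint"):
        out[joint] = JointAngleSeries(
            joint=joint, time_ms=sub["time_ms"].to_numpy(),
            dorsiflexion=sub["dorsiflexion_deg"].to_numpy(),
            eversion=sub["eversion_deg"].to_numpy(),
            external_rotation=sub["external_rotation_deg"].to_numpy(),
            missing=sub["missing"].to_numpy(dtype=bool))
    return out


def write_events(events: TrialEvents, path, note: str = "") -> None:
    Path(path).write_text(json.dumps({
        "toe_contact_ms": events.toe_contact,
        "heel_contact_ms": events.heel_contact,
        "window_start_ms": events.window_start,
        "window_end_ms": events.window_end,
        "late_mark_ms": events.late_mark,
        "detection_note": note or (
            "toe contact: vGRF threshold rule; heel contact: calcaneal "
            "inferior-vertex height rule (package-defined operational "
            "definitions)"),
    }, indent=1))


def read_events(path) -> TrialEvents:
    d = json.loads(Path(path).read_text())
    return TrialEvents(toe_contact=d["toe_contact_ms"],
                       heel_contact=d["heel_contact_ms"])


# -- fluoroscopic frames ----------------------------------------------------

def write_frames(sequence: FluoroSequence, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(sequence.frames):
        arr = np.clip(np.asarray(frame) * 255.0, 0, 255).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(directory / f"frame_{k:04d}.png")
    np.savetxt(directory / "timestamps_ms.csv", sequence.timestamps_ms,
               header="timestamp_ms", comments="")


def read_frames(directory, rate_hz: float = 60.0) -> FluoroSequence:
    directory = Path(directory)
    paths = sorted(directory.glob("frame_*.png"))
    frames = [np.asarray(Image.open(p), dtype=float) / 255.0 for p in paths]
    ts = np.loadtxt(directory / "timestamps_ms.csv", skiprows=1)
    return FluoroSequence(frames=frames, timestamps_ms=np.atleast_1d(ts),
                          rate_hz=rate_hz)


# -- trial directories ------------------------------------------------------

def write_trial_dir(trial, directory) -> None:
    """Write a self-contained synthetic trial directory (meshes, landmarks,
    camera, frames, GRF, ground truth)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ph = trial.phantom
    for bone, mesh in ph.meshes.items():
        write_mesh(mesh, d / f"{bone}.stl")
    write_landmarks(ph.landmarks, d / "landmarks.json")
    write_camera(trial.camera, d / "camera.yaml")
    write_grf(trial.grf, d / "grf.csv")
    if trial.sequence is not None:
        write_frames(trial.sequence, d / "frames")
    truth = {
        "condition": trial.condition,
        "frame_times_ms": trial.frame_times_ms.tolist(),
        "events": {"toe_contact_ms": trial.events.toe_contact,
                   "heel_contact_ms": trial.events.heel_contact},
        "poses": {bone: [p.params().tolist() for p in poses]
                  for bone, poses in trial.truth_poses.items()},
        "angles": {joint: {ax: s.axis(ax).tolist()
                           for ax in ("dorsiflexion", "eversion",
                                      "external_rotation")}
                   for joint, s in trial.truth_angles.items()},
        "peak_vgrf_bw": trial.script.peak_vgrf_bw,
    }
    (d / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def read_trial_dir(directory):
    """Load the parts of a trial directory the analysis pipeline consumes."""
    d = Path(directory)
    meshes = {b: read_mesh(d / f"{b}.stl", name=b)
              for b in ("tibia", "talus", "calcaneus")}
    landmarks = read_landmarks(d / "landmarks.json")
    camera = read_camera(d / "camera.yaml")
    grf = read_grf(d / "grf.csv")
    sequence = read_frames(d / "frames") if (d / "frames").exists() else None
    truth = None
    if (d / "ground_truth.json").exists():
        truth = json.loads((d / "ground_truth.json").read_text())
    return {"meshes": meshes, "landmarks": landmarks, "camera": camera,
            "grf": grf, "sequence": sequence, "ground_truth": truth}
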