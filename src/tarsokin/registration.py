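"""Single-plane fluoroscopic 3D–2D model-image registration.

A bone's 6-DOF pose is recovered by projecting its surface model through a
cone-beam camera, rasterizing the silhouette, and minimizing the mean
distance between the silhouette boundary and the image's edge map (one-way
chamfer cost).  Optimization is a derivative-free Nelder–Mead simplex with
seeded multi-start perturbations; sequences are tracked frame-to-frame with
constant-position prediction.

The lab frame coincides with the camera frame: the optical axis (+z) is the
out-of-plane direction, so in-plane translation = (x, y) and out-of-plane
translation = z.  Depth is only weakly constrained by a single plane, so
out-of-plane repeatability is reported separately and is expected to be an
order of magnitude worse than in-plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import math

import numpy as np
from PIL import Image, ImageDraw
from scipy import ndimage, optimize
from scipy.spatial import ConvexHull
from shapely import geometry as sgeom
from shapely.ops import unary_union
from skimage import measure, morphology

from .anatomy import TriMesh
from .errors import (ContractViolationError, NoEdgesError, ProjectionError)
from .rigid import RigidPose

__all__ = [
    "CameraModel", "FluoroSequence", "RegistrationOptions",
    "RegistrationResult", "RepeatabilityReport",
    "project_point", "project_points", "render_silhouette", "edge_map",
    "pose_cost", "register_frame", "track_sequence", "repeatability",
    "mad_from_mean", "silhouette_samples",
]

IN_PLANE = (3, 4)       # parameter columns tx, ty
OUT_OF_PLANE = (5,)     # tz (optical axis)
ROTATIONS = (0, 1, 2)


@dataclass(frozen=True)
class CameraModel:
    """Cone-beam (point source + flat detector) geometry.

    The optical axis points along +z from the source; the detector plane
    sits ``detector_distance`` mm down the axis.  Image u grows with +x and
    v grows with −y (row 0 is the top of the image).
    """

    source_position: tuple = (0.0, 0.0, 0.0)
    detector_distance: float = 1000.0
    pixel_pitch: float = 1.1
    principal_point: tuple = (128.0, 128.0)
    image_size: tuple = (256, 256)      # (width, height) px

    def __post_init__(self) -> None:
        if self.detector_distance <= 0 or self.pixel_pitch <= 0:
            raise ContractViolationError("detector distance and pitch must be > 0")
        if min(self.image_size) <= 0:
            raise ContractViolationError("image size must be positive")

    def scaled(self, factor: float) -> "CameraModel":
        """Same geometry at a different image resolution (e.g. 0.5 = half)."""
        return CameraModel(
            self.source_position, self.detector_distance,
            self.pixel_pitch / factor,
            tuple(p * factor for p in self.principal_point),
            tuple(int(round(s * factor)) for s in self.image_size))


def project_points(camera: CameraModel, points) -> np.ndarray:
    """Cone-beam projection of (n, 3) mm points to (n, 2) px (u, v)."""
    p = np.atleast_2d(np.asarray(points, dtype=float)) - camera.source_position
    z = p[:, 2]
    if np.any(z <= 1e-9):
        raise ProjectionError("point at or behind the source plane")
    scale = camera.detector_distance / (z * camera.pixel_pitch)
    u = camera.principal_point[0] + p[:, 0] * scale
    v = camera.principal_point[1] - p[:, 1] * scale
    return np.c_[u, v]


def project_point(camera: CameraModel, point) -> np.ndarray:
    """Single-point convenience wrapper around :func:`project_points`."""
    return project_points(camera, np.asarray(point, float).reshape(1, 3))[0]


@dataclass
class FluoroSequence:
    """Grayscale fluoroscopic frames with their timestamps."""

    frames: List[np.ndarray]
    timestamps_ms: np.ndarray
    rate_hz: float = 60.0

    def __post_init__(self) -> None:
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        if len(self.frames) != len(self.timestamps_ms):
            raise ContractViolationError("one timestamp per frame required")
        dt = np.diff(self.timestamps_ms)
        if np.any(dt <= 0):
            raise ContractViolationError("timestamps must be strictly increasing")
        if len(dt) and np.any(np.abs(dt - 1000.0 / self.rate_hz) > 0.1):
            raise ContractViolationError("timestamps inconsistent with frame rate")


def render_silhouette(camera: CameraModel, mesh: TriMesh, pose: RigidPose,
                      return_contour: bool = True):
    """Project the posed mesh and rasterize its filled silhouette.

    Returns ``(mask, contour)``: a boolean image and the ordered (sub-pixel)
    boundary points in (row, col) order from ``skimage.measure.find_contours``
    (``None`` when ``return_contour`` is false).  Raises
    :class:`ProjectionError` when the mesh is behind the source or outside
    the viewing frustum.
    """
    verts = pose.apply(mesh.vertices)
    uv = project_points(camera, verts)
    w, h = camera.image_size
    if (uv[:, 0].min() < 0 or uv[:, 0].max() > w - 1
            or uv[:, 1].min() < 0 or uv[:, 1].max() > h - 1):
        raise ProjectionError("mesh silhouette extends outside the image")
    img = Image.new("1", (w, h), 0)
    draw = ImageDraw.Draw(img)
    tri = uv[mesh.faces]
    for t in tri:
        draw.polygon([(t[0, 0], t[0, 1]), (t[1, 0], t[1, 1]),
                      (t[2, 0], t[2, 1])], fill=1)
    mask = np.asarray(img, dtype=bool)
    if not return_contour:
        return mask, None
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ProjectionError("empty silhouette")
    contour = max(contours, key=len)
    return mask, contour


def render_coverage(camera: CameraModel, mesh: TriMesh, pose: RigidPose,
                    supersample: int = 4) -> np.ndarray:
    """Anti-aliased silhouette: fractional pixel coverage in [0, 1].

    The mask is rasterized at ``supersample``× resolution and box-averaged
    down, so the apparent boundary in the rendered image sits at the true
    projected contour to well under a pixel.
    """
    hi = camera.scaled(supersample)
    mask, _ = render_silhouette(hi, mesh, pose, return_contour=False)
    h, w = mask.shape[0] // supersample, mask.shape[1] // supersample
    return (mask[:h * supersample, :w * supersample]
            .reshape(h, supersample, w, supersample)
            .mean(axis=(1, 3)))


class EdgeDistanceField(np.ndarray):
    """Distance-to-nearest-edge image in *native* pixel units.

    May be stored on a finer grid than the source image (``px_scale``
    samples per native pixel) for sub-pixel edge localization; samplers
    must multiply query coordinates by ``px_scale``.
    """

    px_scale: float = 1.0

    def __array_finalize__(self, obj):
        self.px_scale = getattr(obj, "px_scale", 1.0)


def edge_map(image: np.ndarray, threshold_rel: float = 0.25,
             thin: bool = True, upsample: int = 1) -> EdgeDistanceField:
    """Euclidean distance transform of the image's gradient edges (px).

    Edges are pixels whose Sobel gradient magnitude exceeds
    ``threshold_rel`` times the maximum magnitude; by default the edge
    bands are skeletonized to single-pixel ridges so the chamfer cost has
    a sharp minimum.  The threshold is relative, so the map is invariant
    to affine intensity rescaling.  ``upsample`` > 1 localizes the ridge
    on a finer grid (distance values stay in native px units).
    """
    img = np.asarray(image, dtype=float)
    if img.max() - img.min() <= 1e-12:
        raise NoEdgesError("image has no edges (constant image?)")
    if upsample > 1:
        img = ndimage.zoom(img, upsample, order=3)
    gx = ndimage.sobel(img, axis=1)
    gy = ndimage.sobel(img, axis=0)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak <= 1e-12:
        raise NoEdgesError("image has no edges (constant image?)")
    edges = mag >= threshold_rel * peak
    if thin:
        edges = morphology.skeletonize(edges)
        if not edges.any():
            raise NoEdgesError("edge skeleton is empty")
    dt = ndimage.distance_transform_edt(~edges) / upsample
    field = dt.view(EdgeDistanceField)
    field.px_scale = float(upsample)
    return field


def _densify_polygon(coords: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Sample a closed polygon boundary at ~``spacing`` px intervals."""
    pts = [np.asarray(coords[:1], dtype=float)]
    for a, b in zip(coords[:-1], coords[1:]):
        seg = np.asarray(b, dtype=float) - a
        length = float(np.hypot(*seg))
        n = max(1, int(math.ceil(length / spacing)))
        ts = np.arange(1, n + 1) / n
        pts.append(a + ts[:, None] * seg)
    return np.vstack(pts)


def silhouette_samples(camera: CameraModel, mesh: TriMesh, pose: RigidPose,
                       spacing_px: float = 1.0) -> np.ndarray:
    """(n, 2) sub-pixel (u, v) samples along the silhouette boundary.

    When the mesh declares convex components, the silhouette is computed
    exactly as the union of the components' projected convex hulls (the
    cone-beam image of a convex solid is the convex hull of its projected
    vertices); otherwise it falls back to the rasterized contour.
    """
    if mesh.convex_components is None:
        _, contour = render_silhouette(camera, mesh, pose)
        return contour[:, ::-1]                 # (row, col) -> (u, v)
    verts = pose.apply(mesh.vertices)
    uv = project_points(camera, verts)
    w, h = camera.image_size
    if (uv[:, 0].min() < 0 or uv[:, 0].max() > w - 1
            or uv[:, 1].min() < 0 or uv[:, 1].max() > h - 1):
        raise ProjectionError("mesh silhouette extends outside the image")
    polys = []
    for idx in mesh.convex_components:
        hull = ConvexHull(uv[np.asarray(idx)])
        polys.append(sgeom.Polygon(uv[np.asarray(idx)][hull.vertices]))
    union = unary_union(polys)
    geoms = union.geoms if hasattr(union, "geoms") else [union]
    samples = [_densify_polygon(np.asarray(g.exterior.coords), spacing_px)
               for g in geoms]
    return np.vstack(samples)


@dataclass(frozen=True)
class RegistrationOptions:
    n_starts: int = 5
    start_sigma_mm: float = 1.0
    start_sigma_deg: float = 1.0
    max_evals: int = 400
    xatol: float = 0.02
    fatol: float = 1e-3
    converged_cost_px: float = 0.75
    retry_cost_px: float = 0.45     # tracking: broaden the search above this
    edge_upsample: int = 4
    seed: int = 0


@dataclass
class RegistrationResult:
    """Per-frame, per-bone registration output for one sequence."""

    poses: Dict[str, List[Optional[RigidPose]]]
    costs: Dict[str, np.ndarray]
    converged: Dict[str, np.ndarray]

    def masked_poses(self) -> Dict[str, List[Optional[RigidPose]]]:
        """Poses with non-converged frames replaced by ``None``."""
        return {b: [p if ok else None
                    for p, ok in zip(ps, self.converged[b])]
                for b, ps in self.poses.items()}


@dataclass(frozen=True)
class RepeatabilityReport:
    """Mean absolute deviation from the per-item mean, by DOF group."""

    in_plane_translation_mm: float
    out_of_plane_translation_mm: float
    rotations_deg: float
    per_dof: np.ndarray     # (6,) MAD for (rx, ry, rz, tx, ty, tz)


def pose_cost(camera: CameraModel, mesh: TriMesh, pose: RigidPose,
              edge_dt: np.ndarray) -> float:
    """Mean edge distance (px) along the model's silhouette boundary,
    sampled from the distance map with bilinear interpolation."""
    uv = silhouette_samples(camera, mesh, pose)
    s = getattr(edge_dt, "px_scale", 1.0)
    vals = ndimage.map_coordinates(np.asarray(edge_dt),
                                   [uv[:, 1] * s, uv[:, 0] * s],
                                   order=1, mode="nearest")
    return float(vals.mean())


_FAIL_COST = 1e6


def _safe_cost(camera, mesh, pose, edge_dt) -> float:
    try:
        return pose_cost(camera, mesh, pose, edge_dt)
    except ProjectionError:
        return _FAIL_COST


def register_frame(camera: CameraModel, mesh: TriMesh, image: np.ndarray,
                   init: RigidPose,
                   opts: RegistrationOptions = RegistrationOptions(),
                   edge_dt: Optional[np.ndarray] = None):
    """Recover the bone pose in one frame by chamfer minimization.

    Six parameters (three extrinsic x-y-z rotations in degrees applied on
    top of ``init``'s rotation, three translations in mm) are minimized by
    Nelder–Mead from ``opts.n_starts`` seeded perturbations of ``init``.
    Returns ``(pose, cost, converged)``; ``converged`` is False when the
    best cost stays above ``opts.converged_cost_px``.
    """
    if edge_dt is None:
        edge_dt = edge_map(image, upsample=opts.edge_upsample)
    rng = np.random.default_rng(opts.seed)

    R0, t0 = init.rotation, init.translation

    def pose_of(params):
        delta = RigidPose.from_euler_deg(params[:3], params[3:])
        return RigidPose(delta.rotation @ R0, t0 + delta.translation,
                         _skip_check=True)

    def fun(params):
        return _safe_cost(camera, mesh, pose_of(params), edge_dt)

    best = None
    for s in range(opts.n_starts):
        if s == 0:
            x0 = np.zeros(6)
        else:
            x0 = np.concatenate([
                rng.normal(0.0, opts.start_sigma_deg, 3),
                rng.normal(0.0, opts.start_sigma_mm, 3)])
        res = optimize.minimize(
            fun, x0, method="Nelder-Mead",
            options={"maxfev": opts.max_evals, "xatol": opts.xatol,
                     "fatol": opts.fatol,
                     "initial_simplex": _init_simplex(x0)})
        if best is None or res.fun < best.fun:
            best = res
    # fine polish from the pooled best: collapses nearby micro-minima so
    # repeated runs agree to well under the reported repeatability
    res = optimize.minimize(
        fun, best.x, method="Nelder-Mead",
        options={"maxfev": opts.max_evals, "xatol": opts.xatol / 2,
                 "fatol": opts.fatol / 10,
                 "initial_simplex": _init_simplex(best.x, 0.25, 0.25)})
    if res.fun <= best.fun:
        best = res
    pose = pose_of(best.x)
    cost = float(best.fun)
    converged = cost <= opts.converged_cost_px
    return pose, cost, converged


def _init_simplex(x0: np.ndarray, rot_step: float = 1.0,
                  trans_step: float = 1.0) -> np.ndarray:
    steps = np.array([rot_step] * 3 + [trans_step] * 3)
    simplex = np.tile(x0, (7, 1))
    simplex[1:] += np.diag(steps)
    return simplex


def track_sequence(camera: CameraModel, meshes: Dict[str, TriMesh],
                   sequence: FluoroSequence,
                   init_poses: Dict[str, RigidPose],
                   opts: RegistrationOptions = RegistrationOptions()
                   ) -> RegistrationResult:
    """Register every bone in every frame, initializing frame k from the
    frame k−1 result (constant-position prediction).

    Frames whose registration fails (no edges, non-convergence) are flagged
    and the tracker carries the last good pose forward as the next
    initialization, so an isolated bad frame does not derail its neighbors.
    """
    n = len(sequence.frames)
    poses = {b: [None] * n for b in meshes}
    costs = {b: np.full(n, np.nan) for b in meshes}
    converged = {b: np.zeros(n, dtype=bool) for b in meshes}
    for bone, mesh in meshes.items():
        current = init_poses[bone]
        bone_tag = sum(bone.encode()) % 1000      # stable across processes
        for k, frame in enumerate(sequence.frames):
            frame_opts = RegistrationOptions(
                **{**opts.__dict__, "seed": opts.seed + 977 * k + bone_tag})
            try:
                dt = edge_map(frame, upsample=opts.edge_upsample)
                pose, cost, ok = register_frame(camera, mesh, frame, current,
                                                frame_opts, edge_dt=dt)
                if cost > opts.retry_cost_px:
                    # likely drifted into a nearby false attractor: retry
                    # with a broader seeded multi-start around the same init
                    wide = RegistrationOptions(
                        **{**frame_opts.__dict__,
                           "n_starts": frame_opts.n_starts + 2,
                           "start_sigma_mm": 2.0 * frame_opts.start_sigma_mm,
                           "start_sigma_deg": 2.0 * frame_opts.start_sigma_deg,
                           "seed": frame_opts.seed + 1})
                    pose2, cost2, ok2 = register_frame(
                        camera, mesh, frame, current, wide, edge_dt=dt)
                    if cost2 < cost:
                        pose, cost, ok = pose2, cost2, ok2
            except (NoEdgesError, ProjectionError):
                pose, cost, ok = None, np.nan, False
            poses[bone][k] = pose
            costs[bone][k] = cost
            converged[bone][k] = ok
            if ok:
                current = pose          # constant-position prediction
    return RegistrationResult(poses=poses, costs=costs, converged=converged)


def mad_from_mean(repeats, axis: int = 0) -> np.ndarray:
    """Mean absolute deviation of repeated measurements from their mean,
    taken along ``axis`` (the repeats axis)."""
    X = np.asarray(repeats, dtype=float)
    if X.shape[axis] < 2:
        raise ContractViolationError("need at least 2 repeats")
    return np.abs(X - X.mean(axis=axis, keepdims=True)).mean(axis=axis)


def repeatability(repeated_params: np.ndarray) -> RepeatabilityReport:
    """Repeatability of repeated registrations.

    ``repeated_params`` has shape (repeats, items, 6) with columns
    (rx, ry, rz, tx, ty, tz), rotations in degrees.  For each item and DOF
    the absolute deviation of each repeat from the per-item mean is
    computed, then averaged over repeats and items, and reported separately
    for in-plane translations (x, y), out-of-plane translation (z) and
    rotations.
    """
    X = np.asarray(repeated_params, dtype=float)
    if X.ndim == 2 and X.shape[1] == 6:
        X = X[:, None, :]                  # single item
    if X.ndim != 3 or X.shape[2] != 6 or X.shape[0] < 2:
        raise ContractViolationError("need ≥2 repeats of an (items, 6) array")
    per_dof = mad_from_mean(X, axis=0).mean(axis=0)
    return RepeatabilityReport(
        in_plane_translation_mm=float(per_dof[list(IN_PLANE)].mean()),
        out_of_plane_translation_mm=float(per_dof[list(OUT_OF_PLANE)].mean()),
        rotations_deg=float(per_dof[list(ROTATIONS)].mean()),
        per_dof=per_dof)
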