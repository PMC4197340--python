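"""Anatomical coordinate frames for the distal tibia, talus and calcaneus.

Frames are built from operator-identified landmarks on triangulated bone
surface models, following the standard fluoroscopic ankle conventions:

* tibia — origin at the centroid of the tibial plafond boundary, Y along
  the shaft, X perpendicular to the anteromedial–anterolateral plafond
  edge line (pointing anteriorly);
* talus — origin at the centre of the circle circumscribing the trochlea
  tali, Z along the circle normal (pointing laterally), X along the
  posterior→anterior trochlear edge direction;
* calcaneus — origin at the midpoint between the most lateral point of
  the posterior articular surface and the most medial point of the middle
  articular surface, X parallel to the inferior surface, Y parallel to
  the lateral surface.

All frames are right-handed with X anterior, Y proximal and Z lateral
(right foot).  Primary axes are taken exactly as defined; secondary axes
are Gram–Schmidt-orthogonalised against them; the third axis completes
the right-handed triad.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping

import numpy as np

from .errors import ContractViolationError, DegenerateGeometryError

__all__ = [
    "TriMesh", "LandmarkSet", "AnatomicalFrame", "CircleFit",
    "fit_plane", "fit_circle_3d",
    "build_tibia_frame", "build_talus_frame", "build_calcaneus_frame",
    "build_frame", "REQUIRED_LANDMARKS",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TriMesh:
    """Triangulated bone surface in model coordinates (mm).

    ``convex_components`` optionally lists vertex-index groups whose convex
    hulls union to the solid; registration exploits this for exact
    (sub-pixel) silhouette contours.  ``None`` means unknown shape and
    forces rasterized contours.
    """

    vertices: np.ndarray        # (n, 3) float
    faces: np.ndarray           # (m, 3) int
    name: str = ""              # tibia | talus | calcaneus
    convex_components: object = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) < 4:
            raise ContractViolationError("mesh needs at least 4 vertices")
        if self.faces.min(initial=0) < 0 or self.faces.max(initial=0) >= len(self.vertices):
            raise ContractViolationError("face indices out of range")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        if np.any(areas <= 1e-12):
            raise ContractViolationError("mesh contains degenerate faces")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def transformed(self, pose) -> "TriMesh":
        return TriMesh(pose.apply(self.vertices), self.faces.copy(), self.name,
                       self.convex_components)


REQUIRED_LANDMARKS: Dict[str, tuple] = {
    "tibia": ("plafond_boundary", "shaft_point",
              "anteromedial_edge", "anterolateral_edge"),
    "talus": ("trochlear_surface", "anteromedial_edge", "anterolateral_edge",
              "posteromedial_edge", "posterolateral_edge",
              "anterior_edge", "posterior_edge"),
    "calcaneus": ("posterior_lateral_articular", "middle_medial_articular",
                  "inferior_surface", "lateral_surface", "anterior_point"),
}

_MULTI = {"plafond_boundary", "trochlear_surface",
          "inferior_surface", "lateral_surface"}
_MIN_MULTI = {"plafond_boundary": 3, "trochlear_surface": 3,
              "inferior_surface": 3, "lateral_surface": 3}


@dataclass
class LandmarkSet:
    """Labelled anatomical points, in mm, in the mesh's model coordinates.

    Single landmarks are (3,) arrays; surface/boundary samples are (n, 3).
    """

    bone: str
    points: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bone not in REQUIRED_LANDMARKS:
            raise ContractViolationError(f"unknown bone {self.bone!r}")
        self.points = {k: np.asarray(v, dtype=float) for k, v in self.points.items()}
        for label in REQUIRED_LANDMARKS[self.bone]:
            if label not in self.points:
                raise ContractViolationError(
                    f"{self.bone}: missing required landmark {label!r}")
            p = self.points[label]
            if label in _MULTI:
                p = p.reshape(-1, 3)
                if len(p) < _MIN_MULTI[label]:
                    raise ContractViolationError(
                        f"{self.bone}: {label!r} needs ≥{_MIN_MULTI[label]} points")
            else:
                p = p.reshape(3)
            self.points[label] = p

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    def validate_against(self, mesh: TriMesh, expand: float = 0.10) -> None:
        """All landmarks must lie within the mesh bounding box grown by 10 %."""
        lo, hi = mesh.bounds
        margin = (hi - lo) * expand
        lo, hi = lo - margin, hi + margin
        for label, p in self.points.items():
            pts = np.atleast_2d(p)
            if np.any(pts < lo) or np.any(pts > hi):
                raise ContractViolationError(
                    f"{self.bone}: landmark {label!r} outside expanded bounding box")

    def transformed(self, pose) -> "LandmarkSet":
        return LandmarkSet(self.bone,
                           {k: pose.apply(v) for k, v in self.points.items()})


@dataclass
class AnatomicalFrame:
    """Origin (mm) and a 3x3 matrix whose *rows* are the unit X, Y, Z axes."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise ContractViolationError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ContractViolationError("frame is left-handed")

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    def to_pose(self):
        """Rigid map model coords → anatomical coords."""
        from .rigid import RigidPose
        return RigidPose(self.axes, -self.axes @ self.origin, _skip_check=True)

    def transformed(self, pose) -> "AnatomicalFrame":
        """The same frame after rigidly moving the underlying bone."""
        return AnatomicalFrame(pose.apply(self.origin),
                               self.axes @ pose.rotation.T)


@dataclass
class CircleFit:
    center: np.ndarray
    radius: float
    normal: np.ndarray
    rms_residual: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        self.normal = np.asarray(self.normal, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ContractViolationError("circle radius must be positive")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ContractViolationError("circle normal must be unit length")


# ---------------------------------------------------------------------------
# geometric fits
# ---------------------------------------------------------------------------

def _unit(v: np.ndarray, what: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"zero-length {what}")
    return v / n


def fit_plane(points, orientation_hint=None):
    """Least-squares plane through ``points``.

    Returns ``(point_on_plane, unit_normal)`` where the point is the
    centroid.  The normal sign is chosen to have positive component along
    ``orientation_hint`` when given.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    centroid = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - centroid)
    # collinear: second singular value vanishes relative to the first
    if s[1] <= 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("points are collinear; plane undefined")
    normal = vt[2]
    if orientation_hint is not None and np.dot(normal, orientation_hint) < 0:
        normal = -normal
    return centroid, normal


def fit_circle_3d(points, orientation_hint=None) -> CircleFit:
    """Circle through ≥3 non-collinear 3-D points.

    Fits the least-squares plane first, projects the points into it, then
    solves the algebraic (Kåsa) least-squares circle in-plane.  The
    returned normal follows ``orientation_hint`` when given.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    centroid, normal = fit_plane(pts, orientation_hint)
    # in-plane orthonormal basis
    e1 = _unit(np.cross(normal, [1.0, 0.0, 0.0])
               if abs(normal[0]) < 0.9 else np.cross(normal, [0.0, 1.0, 0.0]))
    e2 = np.cross(normal, e1)
    rel = pts - centroid
    uv = np.c_[rel @ e1, rel @ e2]
    # Kåsa: minimise ||u^2+v^2 - 2au - 2bv - c||
    A = np.c_[2 * uv, np.ones(len(uv))]
    b = (uv ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    a, bb, c = sol
    r2 = c + a * a + bb * bb
    if r2 <= 0:
        raise DegenerateGeometryError("circle fit collapsed (non-positive radius)")
    radius = float(np.sqrt(r2))
    center = centroid + a * e1 + bb * e2
    resid = np.linalg.norm(uv - [a, bb], axis=1) - radius
    return CircleFit(center=center, radius=radius, normal=normal,
                     rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def _orthonormal_triad(primary, secondary, order):
    """Assemble a right-handed frame from a primary axis (kept exact) and a
    secondary axis (Gram–Schmidt-orthogonalised against the primary).

    ``order`` names the rows, e.g. ``("y", "x")`` means primary is Y and
    secondary is X; the remaining axis is the cross product chosen to make
    the (X, Y, Z) rows right-handed.
    """
    p = _unit(np.asarray(primary, float), "primary axis")
    s = np.asarray(secondary, float) - np.dot(secondary, p) * p
    s = _unit(s, "secondary axis (parallel to primary?)")
    axes = {order[0]: p, order[1]: s}
    missing = ({"x", "y", "z"} - set(order)).pop()
    # right-handed: x × y = z, y × z = x, z × x = y
    cross_rule = {"x": ("y", "z"), "y": ("z", "x"), "z": ("x", "y")}
    a, b = cross_rule[missing]
    axes[missing] = np.cross(axes[a], axes[b])
    return AnatomicalFrame(np.zeros(3), np.vstack([axes["x"], axes["y"], axes["z"]]))


# ---------------------------------------------------------------------------
# frame builders
# ---------------------------------------------------------------------------

def build_tibia_frame(mesh: TriMesh, lm: LandmarkSet) -> AnatomicalFrame:
    """Tibial frame: origin at the plafond-boundary centroid, Y toward the
    shaft, X perpendicular to the AM–AL plafond edge line, anterior."""
    if lm.bone != "tibia":
        raise ContractViolationError("tibia landmarks required")
    lm.validate_against(mesh)
    origin = lm["plafond_boundary"].mean(axis=0)
    shaft = lm["shaft_point"] - origin
    if np.linalg.norm(shaft) < 1e-9:
        raise DegenerateGeometryError("shaft point coincides with plafond centroid")
    y = _unit(shaft)
    am, al = lm["anteromedial_edge"], lm["anterolateral_edge"]
    edge = al - am
    if np.linalg.norm(edge) < 1e-9:
        raise DegenerateGeometryError("AM and AL plafond edges coincide")
    x = np.cross(y, edge)          # ⊥ both Y and the AM–AL line
    # anterior disambiguation: the AM–AL edge midpoint sits anterior to the
    # plafond centroid, independent of the AM/AL labelling order
    hint = 0.5 * (am + al) - origin
    if np.dot(x, hint) < 0:
        x = -x
    frame = _orthonormal_triad(y, x, ("y", "x"))
    return AnatomicalFrame(origin, frame.axes)


def build_talus_frame(mesh: TriMesh, lm: LandmarkSet) -> AnatomicalFrame:
    """Talar frame: origin at the centre of the circle circumscribing the
    trochlea tali, Z along the circle normal (lateral), X along the
    posterior→anterior trochlear edge direction."""
    if lm.bone != "talus":
        raise ContractViolationError("talus landmarks required")
    lm.validate_against(mesh)
    mid_ant = 0.5 * (lm["anteromedial_edge"] + lm["anterolateral_edge"])
    mid_post = 0.5 * (lm["posteromedial_edge"] + lm["posterolateral_edge"])
    circle_pts = np.vstack([mid_ant, mid_post, lm["trochlear_surface"]])
    if len(circle_pts) < 3:
        raise DegenerateGeometryError("need at least 3 circle points")
    lateral_hint = (0.5 * (lm["anterolateral_edge"] + lm["posterolateral_edge"])
                    - 0.5 * (lm["anteromedial_edge"] + lm["posteromedial_edge"]))
    fit = fit_circle_3d(circle_pts, orientation_hint=lateral_hint)
    x_dir = lm["anterior_edge"] - lm["posterior_edge"]
    frame = _orthonormal_triad(fit.normal, x_dir, ("z", "x"))
    return AnatomicalFrame(fit.center, frame.axes)


def build_calcaneus_frame(mesh: TriMesh, lm: LandmarkSet) -> AnatomicalFrame:
    """Calcaneal frame: origin midway between the named posterior/middle
    articular points, X parallel to the inferior surface (anterior), Y
    parallel to the lateral surface (proximal)."""
    if lm.bone != "calcaneus":
        raise ContractViolationError("calcaneus landmarks required")
    lm.validate_against(mesh)
    p_lat = lm["posterior_lateral_articular"]
    m_med = lm["middle_medial_articular"]
    if np.linalg.norm(p_lat - m_med) < 1e-9:
        raise DegenerateGeometryError("articular landmark points coincide")
    origin = 0.5 * (p_lat + m_med)
    centroid = mesh.vertices.mean(axis=0)

    inf_centroid, inf_normal = fit_plane(lm["inferior_surface"])
    if np.dot(inf_normal, centroid - inf_centroid) < 0:
        inf_normal = -inf_normal            # proximal (toward the bone)
    lat_centroid, lat_normal = fit_plane(lm["lateral_surface"])
    if np.dot(lat_normal, centroid - lat_centroid) > 0:
        lat_normal = -lat_normal            # outward (lateral)

    ant_hint = lm["anterior_point"] - origin
    x = ant_hint - np.dot(ant_hint, inf_normal) * inf_normal
    x = _unit(x, "calcaneal X (anterior hint ⊥ inferior plane?)")
    y_hint = inf_normal - np.dot(inf_normal, lat_normal) * lat_normal
    frame = _orthonormal_triad(x, y_hint, ("x", "y"))
    # for a right foot (X anterior, Y proximal) the right-handed Z is lateral;
    # a medial Z means the landmark set is not a right foot
    if np.dot(frame.z, lat_normal) < 0:
        raise ContractViolationError(
            "calcaneal landmarks are inconsistent with a right foot "
            "(right-handed Z is not lateral)")
    return AnatomicalFrame(origin, frame.axes)


_BUILDERS = {
    "tibia": build_tibia_frame,
    "talus": build_talus_frame,
    "calcaneus": build_calcaneus_frame,
}


def build_frame(mesh: TriMesh, lm: LandmarkSet) -> AnatomicalFrame:
    """Dispatch on the landmark set's bone name."""
    return _BUILDERS[lm.bone](mesh, lm)
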