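"""Anatomical frame construction: geometric fits, canonical phantom cases,
rigid equivariance, degenerate inputs."""

import numpy as np
import pytest

from tarsokin.anatomy import (AnatomicalFrame, LandmarkSet, TriMesh,
                              build_calcaneus_frame, build_frame,
                              build_talus_frame, build_tibia_frame,
                              fit_circle_3d, fit_plane)
from tarsokin.errors import ContractViolationError, DegenerateGeometryError
from tarsokin.rigid import RigidPose
from tarsokin.synthetic import make_phantom


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    return RigidPose.from_euler_deg(rng.uniform(-180, 180, 3),
                                    rng.uniform(-200, 200, 3))


# ---------------------------------------------------------------------------
# plane fit
# ---------------------------------------------------------------------------

class TestFitPlane:
    def test_exact_plane_with_hint(self):
        pts = [[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]
        _, n = fit_plane(pts, orientation_hint=[0, 0, 1])
        np.testing.assert_allclose(n, [0, 0, 1], atol=1e-12)
        _, n = fit_plane(pts, orientation_hint=[0, 0, -1])
        np.testing.assert_allclose(n, [0, 0, -1], atol=1e-12)

    def test_jittered_plane_is_least_squares_optimal(self):
        """SVD normal must beat a brute-force grid search over directions."""
        rng = np.random.default_rng(7)
        pts = np.c_[rng.uniform(-10, 10, 40), rng.uniform(-10, 10, 40),
                    rng.normal(0, 0.05, 40)]
        centroid, n = fit_plane(pts, orientation_hint=[0, 0, 1])
        assert np.degrees(np.arccos(abs(n[2]))) < 1.0   # ε-proportional tilt

        def ssr(normal):
            normal = normal / np.linalg.norm(normal)
            return np.sum(((pts - pts.mean(0)) @ normal) ** 2)

        best = min(ssr(np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p),
                                 np.cos(t)]))
                   for t in np.linspace(0, np.pi / 8, 60)
                   for p in np.linspace(0, 2 * np.pi, 120))
        assert ssr(n) <= best + 1e-12

    def test_collinear_points_raise(self):
        with pytest.raises(DegenerateGeometryError):
            fit_plane([[0, 0, 0], [1, 1, 1], [2, 2, 2]])


# ---------------------------------------------------------------------------
# circle fit
# ---------------------------------------------------------------------------

class TestFitCircle:
    def test_three_exact_points(self):
        ang = np.radians([10.0, 130.0, 250.0])
        pts = np.c_[20 * np.cos(ang), 20 * np.sin(ang), np.zeros(3)]
        fit = fit_circle_3d(pts, orientation_hint=[0, 0, 1])
        np.testing.assert_allclose(fit.center, [0, 0, 0], atol=1e-9)
        assert fit.radius == pytest.approx(20.0, abs=1e-9)
        assert fit.rms_residual == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("radius", [5.0, 12.5, 27.0, 50.0])
    def test_exact_circles_any_radius(self, radius):
        ang = np.linspace(0, 2 * np.pi, 17, endpoint=False)
        pts = np.c_[3 + radius * np.cos(ang), -2 + radius * np.sin(ang),
                    np.full(17, 4.0)]
        fit = fit_circle_3d(pts, orientation_hint=[0, 0, 1])
        np.testing.assert_allclose(fit.center, [3, -2, 4], atol=1e-9)
        assert fit.radius == pytest.approx(radius, abs=1e-9)
        assert fit.rms_residual < 1e-9

    def test_noisy_circle_matches_grid_search_oracle(self):
        rng = np.random.default_rng(42)
        ang = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.c_[19 * np.cos(ang), 19 * np.sin(ang), np.zeros(12)]
        pts += rng.normal(0, 0.1, pts.shape)
        fit = fit_circle_3d(pts, orientation_hint=[0, 0, 1])

        uv = pts[:, :2]

        def cost(cx, cy, r):
            return np.sum((np.hypot(uv[:, 0] - cx, uv[:, 1] - cy) - r) ** 2)

        grid = np.arange(-0.5, 0.5001, 0.025)
        rgrid = np.arange(18.5, 19.5001, 0.025)
        best = min(((cost(cx, cy, r), cx, cy, r)
                    for cx in grid for cy in grid for r in rgrid))
        assert np.hypot(fit.center[0] - best[1],
                        fit.center[1] - best[2]) < 0.2

    def test_rigid_equivariance(self):
        ang = np.linspace(0, np.pi, 9)
        pts = np.c_[15 * np.cos(ang), 15 * np.sin(ang), np.zeros(9)]
        T = random_rigid(3)
        fit = fit_circle_3d(pts, orientation_hint=[0, 0, 1])
        fit_t = fit_circle_3d(T.apply(pts),
                              orientation_hint=T.rotation @ [0, 0, 1])
        np.testing.assert_allclose(fit_t.center, T.apply(fit.center),
                                   atol=1e-9)
        np.testing.assert_allclose(fit_t.normal, T.rotation @ fit.normal,
                                   atol=1e-9)
        assert fit_t.radius == pytest.approx(fit.radius, abs=1e-9)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle_3d([[0, 0, 0], [1, 0, 0], [2, 0, 0]])


# ---------------------------------------------------------------------------
# frame builders on the phantom
# ---------------------------------------------------------------------------

class TestFrameBuilders:
    def test_tibia_canonical(self, phantom):
        f = phantom.frames["tibia"]
        np.testing.assert_allclose(f.origin, 0.0, atol=1e-9)
        np.testing.assert_allclose(f.axes, np.eye(3), atol=1e-9)

    def test_talus_circle_center_on_cylinder_axis(self, phantom):
        f = phantom.frames["talus"]
        # trochlea is an analytic cylinder about the model z axis
        assert np.hypot(f.origin[0], f.origin[1]) < 0.1
        angle = np.degrees(np.arccos(abs(f.z[2])))
        assert angle < 0.5

    def test_calcaneus_axes_parallel_surfaces(self, phantom):
        f = phantom.frames["calcaneus"]
        incline = np.radians(phantom.spec.calc_incline_deg)
        inf_normal = np.array([-np.sin(incline), np.cos(incline), 0.0])
        assert abs(np.dot(f.x, inf_normal)) < 1e-6      # X in inferior plane
        assert abs(f.y[2]) < 1e-6                       # Y in lateral plane
        assert f.z[2] > 0.99                            # Z lateral

    @pytest.mark.parametrize("bone", ["tibia", "talus", "calcaneus"])
    def test_rigid_equivariance_100_placements(self, phantom, bone):
        base = build_frame(phantom.meshes[bone], phantom.landmarks[bone])
        for seed in range(100):
            T = random_rigid(seed)
            moved = build_frame(phantom.meshes[bone].transformed(T),
                                phantom.landmarks[bone].transformed(T))
            expected = base.transformed(T)
            np.testing.assert_allclose(moved.origin, expected.origin,
                                       atol=1e-9)
            np.testing.assert_allclose(moved.axes, expected.axes, atol=1e-9)
            # orthonormal right-handed under every placement
            np.testing.assert_allclose(moved.axes @ moved.axes.T, np.eye(3),
                                       atol=1e-9)
            assert np.linalg.det(moved.axes) > 0

    def test_tibia_edge_label_swap_invariance(self, phantom):
        lm = phantom.landmarks["tibia"]
        swapped = LandmarkSet("tibia", {
            **lm.points,
            "anteromedial_edge": lm["anterolateral_edge"],
            "anterolateral_edge": lm["anteromedial_edge"]})
        a = build_tibia_frame(phantom.meshes["tibia"], lm)
        b = build_tibia_frame(phantom.meshes["tibia"], swapped)
        np.testing.assert_allclose(a.axes, b.axes, atol=1e-12)

    def test_degenerate_inputs_raise(self, phantom):
        lm = phantom.landmarks["tibia"]
        bad = LandmarkSet("tibia", {**lm.points,
                                    "shaft_point": lm["plafond_boundary"].mean(0)})
        with pytest.raises(DegenerateGeometryError):
            build_tibia_frame(phantom.meshes["tibia"], bad)
        clm = phantom.landmarks["calcaneus"]
        bad_c = LandmarkSet("calcaneus", {
            **clm.points,
            "middle_medial_articular": clm["posterior_lateral_articular"]})
        with pytest.raises(DegenerateGeometryError):
            build_calcaneus_frame(phantom.meshes["calcaneus"], bad_c)

    def test_missing_landmark_rejected(self):
        with pytest.raises(ContractViolationError):
            LandmarkSet("talus", {"anterior_edge": [0, 0, 0]})


class TestTriMeshContracts:
    def test_too_few_vertices(self):
        with pytest.raises(ContractViolationError):
            TriMesh(np.zeros((3, 3)), np.array([[0, 1, 2]]))

    def test_degenerate_face(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]])
        with pytest.raises(ContractViolationError):
            TriMesh(v, np.array([[0, 1, 2]]))
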