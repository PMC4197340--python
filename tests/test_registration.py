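"""Projection, silhouette rendering, chamfer cost and pose recovery."""

import numpy as np
import pytest
import trimesh

from tarsokin.anatomy import TriMesh
from tarsokin.errors import (ContractViolationError, NoEdgesError,
                             ProjectionError)
from tarsokin.registration import (CameraModel, FluoroSequence,
                                   RegistrationOptions, edge_map,
                                   mad_from_mean, pose_cost, project_point,
                                   register_frame, render_silhouette,
                                   repeatability, silhouette_samples,
                                   track_sequence)
from tarsokin.rigid import RigidPose
from tarsokin.synthetic import render_scene_frame


SIMPLE_CAM = CameraModel(source_position=(0, 0, 0), detector_distance=1000.0,
                         pixel_pitch=0.5, principal_point=(128, 128),
                         image_size=(256, 256))


def cube_mesh(side=20.0):
    m = trimesh.creation.box(extents=(side, side, side))
    return TriMesh(m.vertices, m.faces, "cube",
                   convex_components=[np.arange(len(m.vertices))])


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

class TestProjection:
    def test_point_on_optical_axis_hits_principal_point(self):
        uv = project_point(SIMPLE_CAM, [0, 0, 700])
        np.testing.assert_allclose(uv, [128, 128], atol=1e-12)

    def test_similar_triangles(self):
        # 10 mm off-axis at half the detector distance, pitch 0.5 mm/px:
        # detector offset = 10 * (1000/500) = 20 mm = 40 px
        uv = project_point(SIMPLE_CAM, [10, 0, 500])
        np.testing.assert_allclose(uv, [128 + 40, 128], atol=1e-12)

    def test_magnification_linearity_at_fixed_depth(self):
        a = project_point(SIMPLE_CAM, [5, 0, 800])
        b = project_point(SIMPLE_CAM, [10, 0, 800])
        assert (b[0] - 128) == pytest.approx(2 * (a[0] - 128), abs=1e-9)

    def test_point_behind_source_raises(self):
        with pytest.raises(ProjectionError):
            project_point(SIMPLE_CAM, [0, 0, -5])


# ---------------------------------------------------------------------------
# silhouette rendering
# ---------------------------------------------------------------------------

class TestRenderSilhouette:
    def test_cube_area_matches_analytic_projection(self):
        pose = RigidPose(np.eye(3), [0, 0, 700])
        mask, contour = render_silhouette(SIMPLE_CAM, cube_mesh(), pose)
        # silhouette = projection of the near face (largest magnification)
        side_px = 20.0 * 1000.0 / (690.0 * 0.5)
        assert mask.sum() == pytest.approx(side_px ** 2, rel=0.02)
        assert contour.ndim == 2 and contour.shape[1] == 2

    def test_in_plane_shift_moves_centroid_by_magnification(self):
        pose0 = RigidPose(np.eye(3), [0, 0, 700])
        pose1 = RigidPose(np.eye(3), [5.0, 0, 700])
        m0, _ = render_silhouette(SIMPLE_CAM, cube_mesh(), pose0)
        m1, _ = render_silhouette(SIMPLE_CAM, cube_mesh(), pose1)
        c0 = np.argwhere(m0).mean(0)
        c1 = np.argwhere(m1).mean(0)
        expected = 5.0 * 1000.0 / (700.0 * 0.5)
        assert (c1 - c0)[1] == pytest.approx(expected, abs=0.5)
        assert abs((c1 - c0)[0]) < 0.5

    def test_mesh_behind_source_raises(self):
        with pytest.raises(ProjectionError):
            render_silhouette(SIMPLE_CAM, cube_mesh(),
                              RigidPose(np.eye(3), [0, 0, -300]))

    def test_hull_contour_agrees_with_rasterized_contour(self):
        pose = RigidPose.from_euler_deg([20, 35, 10], [5, -8, 700])
        mesh = cube_mesh()
        samples = silhouette_samples(SIMPLE_CAM, mesh, pose)
        raster = TriMesh(mesh.vertices, mesh.faces, "cube")  # no components
        rsamples = silhouette_samples(SIMPLE_CAM, raster, pose)
        from scipy.spatial import cKDTree
        d = cKDTree(samples).query(rsamples)[0]
        assert d.max() < 1.5        # rasterization quantizes to pixel edges


# ---------------------------------------------------------------------------
# edge map
# ---------------------------------------------------------------------------

class TestEdgeMap:
    def test_vertical_step_edge_distance(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 1.0
        dt = edge_map(img)
        cols = np.arange(64)
        expected = np.abs(cols - 32)
        # interior rows, away from image border artefacts
        measured = dt[32]
        assert np.abs(measured[2:-2] - expected[2:-2]).max() <= 1.0

    def test_distance_transform_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.random((64, 64))
        img = np.cumsum(img, axis=1) / 32.0     # smooth-ish gradient image
        dt = edge_map(img, thin=False)
        # recompute the same edge set and brute-force nearest distances
        from scipy import ndimage
        mag = np.hypot(ndimage.sobel(img, 1), ndimage.sobel(img, 0))
        edges = np.argwhere(mag >= 0.25 * mag.max())
        yy, xx = np.mgrid[0:64, 0:64]
        brute = np.sqrt(((yy[..., None] - edges[:, 0]) ** 2
                         + (xx[..., None] - edges[:, 1]) ** 2).min(-1))
        np.testing.assert_allclose(np.asarray(dt), brute, atol=1e-9)

    def test_constant_image_raises(self):
        with pytest.raises(NoEdgesError):
            edge_map(np.full((32, 32), 0.7))


# ---------------------------------------------------------------------------
# pose cost
# ---------------------------------------------------------------------------

class TestPoseCost:
    def test_self_render_cost_small(self, phantom, landing_trial, contact_frame):
        img, dt = contact_frame
        for bone in ("tibia", "talus", "calcaneus"):
            cost = pose_cost(landing_trial.camera, phantom.meshes[bone],
                             landing_trial.truth_poses[bone][0], dt)
            assert cost < 0.75

    def test_shifted_pose_costs_more(self, phantom, landing_trial, contact_frame):
        img, dt = contact_frame
        truth = landing_trial.truth_poses["talus"][0]
        shifted = RigidPose(truth.rotation, truth.translation + [5.0, 0, 0])
        assert (pose_cost(landing_trial.camera, phantom.meshes["talus"],
                          shifted, dt)
                > pose_cost(landing_trial.camera, phantom.meshes["talus"],
                            truth, dt))

    def test_cost_invariant_to_intensity_rescaling(self, phantom,
                                                   landing_trial):
        img = landing_trial.sequence.frames[0]
        truth = landing_trial.truth_poses["talus"][0]
        c1 = pose_cost(landing_trial.camera, phantom.meshes["talus"], truth,
                       edge_map(img, upsample=2))
        c2 = pose_cost(landing_trial.camera, phantom.meshes["talus"], truth,
                       edge_map(0.5 * img + 0.25, upsample=2))
        assert c2 == pytest.approx(c1, abs=1e-9)


# ---------------------------------------------------------------------------
# registration
# ---------------------------------------------------------------------------

class TestRegisterFrame:
    def test_ground_truth_recovery_from_perturbed_init(
            self, phantom, landing_trial, contact_frame, rng):
        img, dt = contact_frame
        for bone in ("tibia", "talus", "calcaneus"):
            truth = landing_trial.truth_poses[bone][0]
            init = truth.perturbed(rng, 3.0, 3.0)
            pose, cost, ok = register_frame(
                landing_trial.camera, phantom.meshes[bone], img, init,
                RegistrationOptions(seed=5), edge_dt=dt)
            assert ok
            err = pose.params() - truth.params()
            assert np.abs(err[3:5]).max() < 0.6     # in-plane translations
            assert abs(err[2]) < 0.6                # in-plane rotation
            assert np.abs(err[:3]).max() < 2.5      # all rotations

    def test_descent_from_truth_init(self, phantom, landing_trial,
                                     contact_frame):
        img, dt = contact_frame
        truth = landing_trial.truth_poses["talus"][0]
        c_init = pose_cost(landing_trial.camera, phantom.meshes["talus"],
                           truth, dt)
        _, cost, _ = register_frame(landing_trial.camera,
                                    phantom.meshes["talus"], img, truth,
                                    RegistrationOptions(seed=0, n_starts=2),
                                    edge_dt=dt)
        assert cost <= c_init + 1e-9

    def test_far_init_flags_nonconvergence(self, phantom, landing_trial,
                                           contact_frame):
        img, dt = contact_frame
        truth = landing_trial.truth_poses["talus"][0]
        far = RigidPose(
            RigidPose.from_euler_deg([0, 0, 40], [0, 0, 0]).rotation
            @ truth.rotation,
            truth.translation + [-50.0, 30.0, 0.0])
        _, _, ok = register_frame(landing_trial.camera,
                                  phantom.meshes["talus"], img, far,
                                  RegistrationOptions(seed=0, n_starts=2,
                                                      max_evals=150),
                                  edge_dt=dt)
        assert not ok

    def test_monotone_capture_range(self, phantom, landing_trial,
                                    contact_frame):
        """Median in-plane recovery error is non-decreasing in the
        initialization perturbation magnitude."""
        img, dt = contact_frame
        truth = landing_trial.truth_poses["talus"][0]
        medians = []
        for level, (pdeg, pmm) in enumerate([(1, 1), (8, 8), (25, 25)]):
            rng = np.random.default_rng(100 + level)
            errs = []
            for rep in range(5):
                init = truth.perturbed(rng, pdeg, pmm)
                pose, _, _ = register_frame(
                    landing_trial.camera, phantom.meshes["talus"], img, init,
                    RegistrationOptions(seed=rep, n_starts=2, max_evals=200),
                    edge_dt=dt)
                err = pose.params() - truth.params()
                errs.append(np.abs(err[3:5]).max())
            medians.append(np.median(errs))
        assert medians[0] <= medians[1] + 1e-9 <= medians[2] + 2e-9


class TestTrackSequence:
    def test_static_sequence_repeatability(self, phantom, camera):
        from tarsokin.synthetic import static_reference_poses
        poses = static_reference_poses(phantom)
        rng = np.random.default_rng(0)
        frames = [render_scene_frame(camera, phantom, poses, rng,
                                     noise_sigma=0.01) for _ in range(4)]
        seq = FluoroSequence(frames=frames,
                             timestamps_ms=np.arange(4) * 1000.0 / 60.0)
        init = {"talus": poses["talus"].perturbed(rng, 2.0, 2.0)}
        res = track_sequence(camera, {"talus": phantom.meshes["talus"]},
                             seq, init,
                             RegistrationOptions(seed=1, n_starts=2,
                                                 max_evals=250))
        P = np.array([p.params() for p in res.poses["talus"]])
        spread = mad_from_mean(P, axis=0)
        assert spread[3:5].max() < 0.60      # in-plane translations, mm
        assert spread[:3].max() < 0.59       # rotations, deg

    def test_dropped_black_frame_flagged_neighbors_survive(
            self, phantom, camera):
        from tarsokin.synthetic import static_reference_poses
        poses = static_reference_poses(phantom)
        rng = np.random.default_rng(1)
        frames = [render_scene_frame(camera, phantom, poses, rng,
                                     noise_sigma=0.01) for _ in range(3)]
        frames[1] = np.zeros_like(frames[1])
        seq = FluoroSequence(frames=frames,
                             timestamps_ms=np.arange(3) * 1000.0 / 60.0)
        init = {"talus": poses["talus"].perturbed(rng, 1.0, 1.0)}
        res = track_sequence(camera, {"talus": phantom.meshes["talus"]},
                             seq, init,
                             RegistrationOptions(seed=2, n_starts=2,
                                                 max_evals=250))
        assert not res.converged["talus"][1]
        assert res.poses["talus"][1] is None
        assert res.converged["talus"][0] and res.converged["talus"][2]
        for k in (0, 2):
            err = res.poses["talus"][k].params() - poses["talus"].params()
            assert np.abs(err[3:5]).max() < 0.6


class TestRepeatability:
    def test_hand_arithmetic_three_repeats(self):
        # one DOF, repeats (1, 2, 3): deviations (1, 0, 1) -> mean 2/3
        vals = np.array([1.0, 2.0, 3.0])
        assert mad_from_mean(vals) == pytest.approx(2.0 / 3.0)
        X = np.zeros((3, 1, 6))
        X[:, 0, 3] = vals
        rep = repeatability(X)
        assert rep.per_dof[3] == pytest.approx(2.0 / 3.0)

    def test_identical_repeats_zero(self):
        X = np.tile(np.arange(6.0), (3, 4, 1))
        rep = repeatability(X)
        np.testing.assert_allclose(rep.per_dof, 0.0)

    def test_two_repeats_closed_form(self):
        a, b = 1.3, -0.9
        X = np.zeros((2, 1, 6))
        X[0, 0, 0], X[1, 0, 0] = a, b
        rep = repeatability(X)
        assert rep.per_dof[0] == pytest.approx(abs(a - b) / 2.0)

    def test_single_repeat_rejected(self):
        with pytest.raises(ContractViolationError):
            repeatability(np.zeros((1, 3, 6)))
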