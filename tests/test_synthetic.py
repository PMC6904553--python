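import numpy as np
import pytest
from scipy.spatial import ConvexHull

from navlab.exceptions import InsufficientPosesError, NavlabError
from navlab.geometry import random_rigid_transform
from navlab.handeye import solve_handeye
from navlab.registration import CorrespondenceSet, icp_register, rigid_register_svd
from navlab.synthetic import (
    DeformationModel,
    PhantomConfig,
    TrackingModel,
    UserModel,
    apply_deformation,
    expected_mean_fle,
    generate_camera_trajectory,
    generate_handeye_dataset,
    generate_phantom,
    simulate_annotations,
    simulate_fiducial_insertion,
    simulate_tool_sampling,
)


class TestPhantom:
    def test_same_seed_reproduces_phantom(self):
        a = generate_phantom(PhantomConfig(seed=42))
        b = generate_phantom(PhantomConfig(seed=42))
        assert np.array_equal(a.surface, b.surface)
        assert all(np.array_equal(a.marks[l], b.marks[l]) for l in a.labels)

    def test_mark_spacing_constraint_holds(self, phantom):
        marks = phantom.marks_array()
        d = np.linalg.norm(marks[:, None] - marks[None], axis=2)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= PhantomConfig().min_mark_spacing

    def test_marks_lie_on_anterior_surface(self, phantom):
        marks = phantom.marks_array()
        assert (marks[:, 2] > 0).all()
        assert len(marks) == 15

    def test_volume_within_porcine_liver_range(self, phantom):
        # independent convex-hull oracle straight from scipy
        hull_cm3 = ConvexHull(phantom.surface).volume / 1000.0
        assert 1593.0 <= hull_cm3 <= 2761.0

    def test_infeasible_spacing_errors_after_retries(self):
        with pytest.raises(NavlabError, match="spacing"):
            generate_phantom(PhantomConfig(min_mark_spacing=200.0, seed=1))


class TestDeformation:
    def test_zero_magnitude_is_identity(self, phantom):
        out = apply_deformation(phantom, DeformationModel(magnitude=0.0))
        assert np.array_equal(out.surface, phantom.surface)

    def test_uniform_field_shifts_all_marks_equally(self, phantom):
        # one RBF control point with a near-infinite kernel ~ pure translation
        d = DeformationModel(
            magnitude=10.0, affine_strength=0.0, n_control_points=1, kernel_width=1e9, seed=2
        )
        out = apply_deformation(phantom, d)
        disp = out.marks_array() - phantom.marks_array()
        assert np.allclose(disp, disp[0], atol=1e-6)
        assert np.linalg.norm(disp[0]) == pytest.approx(10.0, rel=1e-6)

    @pytest.mark.parametrize("magnitude", [5.0, 25.0, 40.0])
    def test_mean_mark_displacement_tracks_magnitude(self, phantom, magnitude):
        out = apply_deformation(phantom, DeformationModel(magnitude=magnitude, seed=3))
        disp = np.linalg.norm(out.marks_array() - phantom.marks_array(), axis=1)
        assert disp.mean() == pytest.approx(magnitude, rel=0.2)

    def test_fiducials_follow_marks(self, phantom):
        out = apply_deformation(phantom, DeformationModel(magnitude=20.0, seed=4))
        for l in phantom.labels:
            assert np.allclose(out.marks[l], out.fiducials[l], atol=1e-9)


class TestAnnotations:
    def test_noiseless_unbiased_equals_truth(self, phantom):
        user = UserModel("A", sigma_intraop=0.0)
        ann = simulate_annotations(phantom, user, "intraop", seed=1)
        assert all(np.array_equal(ann[l], phantom.marks[l]) for l in phantom.labels)

    def test_pure_bias_gives_345_fle(self, phantom):
        user = UserModel("A", bias=(3.0, 4.0, 0.0), sigma_intraop=0.0)
        ann = simulate_annotations(phantom, user, "intraop", seed=1)
        for l in phantom.labels:
            assert np.linalg.norm(ann[l] - phantom.marks[l]) == pytest.approx(5.0, abs=1e-12)

    def test_mean_fle_matches_maxwell_mean(self, phantom):
        # sigma 10.5 mm targets a mean FLE of 2*sigma*sqrt(2/pi) ~= 16.75 mm
        user = UserModel("A", sigma_intraop=10.5)
        errs = []
        for seed in range(667):  # ~10^4 mark draws
            ann = simulate_annotations(phantom, user, "intraop", seed=seed)
            errs.extend(np.linalg.norm(ann[l] - phantom.marks[l]) for l in phantom.labels)
        assert np.mean(errs) == pytest.approx(expected_mean_fle(10.5), rel=0.03)

    def test_preop_sigma_defaults_to_ratio(self):
        user = UserModel("A", sigma_intraop=10.0)
        assert user.sigma("preop") == pytest.approx(14.5)
        assert UserModel("B", sigma_intraop=10.0, sigma_preop=12.0).sigma("preop") == 12.0


class TestToolSampling:
    def test_zero_noise_closed_loop_recovers_hidden_transform(self, phantom):
        tracking = TrackingModel(breathing_amplitude=0.0, jitter_sigma=0.0)
        sampled, t_ip = simulate_tool_sampling(phantom, tracking, seed=5)
        corr = CorrespondenceSet(
            phantom.marks_array(),
            np.array([sampled[l] for l in phantom.labels]),
            phantom.labels,
        )
        result = rigid_register_svd(corr)
        assert np.allclose(result.transform.matrix, t_ip.matrix, atol=1e-9)

    def test_breathing_averages_out_over_full_periods(self, phantom):
        tracking = TrackingModel(breathing_amplitude=5.0, jitter_sigma=0.0)
        sampled, t_ip = simulate_tool_sampling(phantom, tracking, seed=6)
        for l in phantom.labels:
            assert np.linalg.norm(sampled[l] - t_ip.apply(phantom.marks[l])) < 1e-9

    def test_jitter_shrinks_as_sqrt_of_samples(self, phantom):
        # sigma 2 mm over 50 samples: per-axis SE 2/sqrt(50)
        tracking = TrackingModel(breathing_amplitude=0.0, jitter_sigma=2.0, n_samples=50)
        errs = []
        for seed in range(100):
            sampled, t_ip = simulate_tool_sampling(phantom, tracking, seed=seed)
            errs.extend(
                np.linalg.norm(sampled[l] - t_ip.apply(phantom.marks[l]))
                for l in phantom.labels
            )
        expected = expected_mean_fle(2.0 / np.sqrt(50))  # mean 3D norm at the shrunken sigma
        assert np.mean(errs) == pytest.approx(expected, rel=0.05)


class TestFiducialInsertion:
    def test_zero_displacement_gives_identical_clouds_and_identity_icp(self, phantom):
        pair = simulate_fiducial_insertion(phantom, 0.0)
        assert np.array_equal(pair.original.surface, pair.displaced.surface)
        t = icp_register(pair.displaced.surface, pair.original.surface)
        assert np.allclose(t.matrix, np.eye(4), atol=1e-9)

    def test_rigid_only_displacement_recovered_by_icp(self, phantom):
        pair = simulate_fiducial_insertion(
            phantom, 0.0, rigid_angle_deg=4.0, rigid_translation_mm=6.0, seed=7
        )
        t = icp_register(pair.displaced.surface, pair.original.surface)
        back = t.apply(pair.displaced.surface)
        assert np.linalg.norm(back - pair.original.surface, axis=1).max() < 0.1

    def test_smooth_perturbation_leaves_bounded_icp_residual(self, phantom):
        pair = simulate_fiducial_insertion(phantom, 3.0, seed=8)
        t = icp_register(pair.displaced.surface, pair.original.surface)
        resid = np.linalg.norm(t.apply(pair.displaced.surface) - pair.original.surface, axis=1)
        assert 0.0 < resid.mean() < 3.0


class TestCameraTrajectory:
    @staticmethod
    def _world(phantom, seed=9, **kwargs):
        rng = np.random.default_rng(seed)
        t_cm = random_rigid_transform(rng, "C", "M", 120.0)
        t_ip = random_rigid_transform(rng, "I", "P", 200.0)
        t_po = random_rigid_transform(rng, "P", "O", 500.0)
        from navlab.geometry import CameraIntrinsics

        k = CameraIntrinsics(800.0, 800.0, 480.0, 270.0, 960, 540)
        frames = generate_camera_trajectory(
            phantom, 10, k, seed=seed, t_ip=t_ip, t_po=t_po, t_cm=t_cm, **kwargs
        )
        return frames, k, t_cm, t_ip, t_po

    def test_noiseless_frames_close_the_loop(self, phantom):
        from navlab.evaluation import compute_tre_frame
        from navlab.geometry import build_ar_chain, invert

        frames, k, t_cm, t_ip, t_po = self._world(phantom)
        for frame in frames:
            chain = build_ar_chain(k, t_cm, frame.t_mo, t_po, invert(t_ip))
            tre, skipped = compute_tre_frame(chain, phantom.marks, frame.centroids)
            assert not skipped
            assert len(tre) == 15  # every mark visible in every frame
            assert max(v for _, v in tre) < 1e-6

    def test_centroid_noise_sets_the_expected_tre_floor(self, phantom):
        # 2 px isotropic 2D noise at depth z and focal length f costs
        # (z/f)*E[,norm of 2D gaussian,] = (z/f)*sigma*sqrt(pi/2) millimetres
        from navlab.evaluation import compute_tre_frame
        from navlab.geometry import build_ar_chain, invert

        sigma_px = 2.0
        frames, k, t_cm, t_ip, t_po = self._world(phantom, seed=11, centroid_noise_px=sigma_px)
        values, depths = [], []
        for frame in frames:
            chain = build_ar_chain(k, t_cm, frame.t_mo, t_po, invert(t_ip))
            tre, _ = compute_tre_frame(chain, phantom.marks, frame.centroids)
            values.extend(v for _, v in tre)
            _, z = chain.project_points(phantom.marks_array())
            depths.extend(z)
        expected = np.mean(depths) / k.fx * sigma_px * np.sqrt(np.pi / 2.0)
        assert np.mean(values) == pytest.approx(expected, rel=0.15)

    def test_same_seed_gives_identical_trajectory(self, phantom):
        a, *_ = self._world(phantom, seed=13)
        b, *_ = self._world(phantom, seed=13)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.t_mo.matrix, fb.t_mo.matrix)
            assert fa.centroids == fb.centroids


class TestHandEyeDataset:
    def test_noiseless_closed_loop(self, rng):
        true = random_rigid_transform(rng, "C", "M", 120.0)
        result = solve_handeye(generate_handeye_dataset(true, 10, seed=17))
        assert np.abs(result.t_cm.rotation - true.rotation).max() < 1e-9
        assert np.linalg.norm(result.t_cm.translation - true.translation) < 1e-9

    def test_two_poses_raise_insufficient(self, rng):
        true = random_rigid_transform(rng, "C", "M", 120.0)
        with pytest.raises(InsufficientPosesError):
            solve_handeye(generate_handeye_dataset(true, 2, seed=19))

    def test_median_recovery_under_moderate_noise(self, rng):
        # 0.5 mm / 0.2 deg pose noise, 30 poses, 50 repetitions
        true = random_rigid_transform(rng, "C", "M", 120.0)
        errs = []
        for rep in range(50):
            pairs = generate_handeye_dataset(true, 30, noise=(0.5, 0.2), seed=100 + rep)
            result = solve_handeye(pairs)
            errs.append(np.linalg.norm(result.t_cm.translation - true.translation))
        assert np.median(errs) < 2.0
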