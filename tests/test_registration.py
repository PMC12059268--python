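"""Transform algebra, metric, samplers, pyramid, optimizers, and the driver."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bonereg.morphology import BinaryMask
from bonereg.phantom import generate
from bonereg.registration import (
    INITIAL,
    OptimizationError,
    PyramidSchedule,
    RigidTransform,
    SamplePointSet,
    build_pyramid,
    gradient_descent_optimize,
    mean_squares_metric,
    powell_optimize,
    register,
    sample_points,
    scales_from_physical_shift,
)
from bonereg.volume import ImageVolume, ParameterError

from conftest import bone_mask, random_rigid, random_volume, single_bone_spec


class TestRigidTransform:
    def test_inverse_round_trip(self, rng):
        for _ in range(10):
            T = random_rigid(rng)
            pts = rng.normal(size=(20, 3)) * 10
            back = T.inverse().apply(T.apply(pts))
            assert np.abs(back - pts).max() < 1e-9

    def test_composition_matches_sequential_application(self, rng):
        A, B = random_rigid(rng), random_rigid(rng, center=(1.0, -2.0, 3.0))
        pts = rng.normal(size=(15, 3)) * 10
        np.testing.assert_allclose(A.compose(B).apply(pts),
                                   A.apply(B.apply(pts)), atol=1e-9)

    def test_composition_associativity(self, rng):
        A, B, C = (random_rigid(rng) for _ in range(3))
        pts = rng.normal(size=(8, 3)) * 5
        np.testing.assert_allclose(
            A.compose(B).compose(C).apply(pts),
            A.compose(B.compose(C)).apply(pts), atol=1e-9)

    def test_versor_and_euler_parameterizations_agree(self, rng):
        for _ in range(10):
            T = random_rigid(rng)
            pts = rng.normal(size=(10, 3)) * 8
            pv = T.parameters("versor")
            pe = T.parameters("euler")
            Tv = RigidTransform.from_parameters(pv, T.center, "versor")
            Te = RigidTransform.from_parameters(pe, T.center, "euler")
            np.testing.assert_allclose(Tv.apply(pts), Te.apply(pts), atol=1e-9)

    def test_recenter_preserves_the_map(self, rng):
        T = random_rigid(rng)
        pts = rng.normal(size=(10, 3)) * 10
        np.testing.assert_allclose(T.recenter([7.0, -3.0, 1.0]).apply(pts),
                                   T.apply(pts), atol=1e-9)

    def test_tfm_round_trip(self, tmp_path, rng):
        T = random_rigid(rng)
        path = tmp_path / "t.tfm"
        T.to_tfm(path)
        back = RigidTransform.from_tfm(path)
        pts = rng.normal(size=(5, 3)) * 10
        np.testing.assert_allclose(back.apply(pts), T.apply(pts), atol=1e-9)
        assert "AffineTransform_double_3_3" in path.read_text()


class TestSamplePoints:
    def _mask(self, data, spacing=(0.9, 0.9, 3.0)):
        return BinaryMask(data, spacing=np.asarray(spacing))

    def test_full_fraction_returns_all_voxel_centers(self, rng):
        data = rng.random((6, 6, 4)) < 0.3
        m = self._mask(data)
        for strategy in ("regular", "random"):
            pts = sample_points(m, strategy, 1.0, seed=0)
            assert len(pts) == data.sum()

    def test_regular_stride(self):
        data = np.zeros((10, 1, 1), dtype=bool)
        data[:, 0, 0] = True
        pts = sample_points(self._mask(data), "regular", 0.5, seed=0)
        assert len(pts) == 5
        np.testing.assert_allclose(pts.points[:, 0], [0, 1.8, 3.6, 5.4, 7.2])

    def test_random_sampling_reproducible_and_seed_sensitive(self, rng):
        data = rng.random((10, 10, 5)) < 0.5
        m = self._mask(data)
        a = sample_points(m, "random", 0.4, seed=3)
        b = sample_points(m, "random", 0.4, seed=3)
        c = sample_points(m, "random", 0.4, seed=4)
        np.testing.assert_array_equal(a.points, b.points)
        assert a.points.shape != c.points.shape or not np.allclose(a.points, c.points)

    def test_invalid_fraction(self, rng):
        m = self._mask(np.ones((3, 3, 3), dtype=bool))
        for f in (0.0, -1.0, 1.5):
            with pytest.raises(ParameterError):
                sample_points(m, "regular", f, 0)


class TestMeanSquaresMetric:
    def test_zero_for_identical_images(self, rng):
        vol = random_volume(rng)
        pts = SamplePointSet(vol.index_to_world(
            rng.integers(2, 13, size=(40, 3)).astype(float)))
        T = RigidTransform.identity()
        assert mean_squares_metric(vol, vol, T, pts) < 1e-12

    def test_constant_offset_gives_squared_constant(self, rng):
        vol = random_volume(rng)
        shifted = vol.with_data(vol.data + 17.0)
        pts = SamplePointSet(vol.index_to_world(
            rng.integers(2, 13, size=(40, 3)).astype(float)))
        got = mean_squares_metric(vol, shifted, RigidTransform.identity(), pts)
        assert abs(got - 17.0 ** 2) < 1e-9

    def test_matches_brute_force_point_loop(self, rng):
        from conftest import brute_force_trilinear

        fixed = random_volume(rng)
        moving = random_volume(rng)
        pts_idx = rng.uniform(1, 14, size=(60, 3))
        pts = SamplePointSet(fixed.index_to_world(pts_idx))
        for _ in range(5):
            T = random_rigid(rng, max_deg=10, max_mm=3)
            got = mean_squares_metric(fixed, moving, T, pts, default_value=-5.0)
            f = brute_force_trilinear(fixed, pts.points, -5.0)
            m = brute_force_trilinear(moving, T.apply(pts.points), -5.0)
            expect = np.mean((f - m) ** 2)
            assert abs(got - expect) < 1e-9

    def test_empty_point_set_rejected(self, rng):
        vol = random_volume(rng)
        with pytest.raises(ParameterError):
            mean_squares_metric(vol, vol, RigidTransform.identity(),
                                SamplePointSet(np.empty((0, 3))))


class TestPyramid:
    def test_trivial_schedule_is_identity(self, rng):
        vol = random_volume(rng)
        sched = PyramidSchedule((1,), (0,), (1.0,))
        (img, _), = build_pyramid(vol, None, sched)
        np.testing.assert_array_equal(img.data, vol.data)

    def test_constant_image_stays_constant(self):
        vol = ImageVolume(np.full((16, 16, 16), 5.0))
        sched = PyramidSchedule((4, 1), (4, 0), (1.0,))
        levels = build_pyramid(vol, None, sched)
        assert np.allclose(levels[0][0].data, 5.0, atol=1e-6)

    def test_shrink_two_geometry(self, rng):
        vol = random_volume(rng, shape=(16, 16, 16), spacing=(0.9, 0.9, 3.0))
        sched = PyramidSchedule((2,), (0,), (1.0,))
        (img, _), = build_pyramid(vol, None, sched)
        assert img.shape == (8, 8, 8)
        np.testing.assert_allclose(img.spacing, [1.8, 1.8, 6.0])
        np.testing.assert_allclose(img.index_to_world([0, 0, 0]),
                                   vol.index_to_world([0, 0, 0]), atol=1e-12)
        np.testing.assert_allclose(img.index_to_world([1, 0, 0]),
                                   vol.index_to_world([2, 0, 0]), atol=1e-12)

    def test_masks_subsampled_never_smoothed(self, rng):
        vol = random_volume(rng)
        mask = BinaryMask(rng.random(vol.shape) < 0.4, spacing=vol.spacing,
                          origin=vol.origin)
        sched = PyramidSchedule((2,), (3,), (1.0,))
        (_, m), = build_pyramid(vol, mask, sched)
        np.testing.assert_array_equal(m.data, mask.data[::2, ::2, ::2])

    def test_oversized_shrink_rejected(self, rng):
        vol = random_volume(rng, shape=(8, 8, 8))
        with pytest.raises(ParameterError):
            build_pyramid(vol, None, PyramidSchedule((16,), (0,), (1.0,)))


class TestScalesFromPhysicalShift:
    def test_translation_parameters_have_unit_scale(self, rng):
        pts = SamplePointSet(rng.normal(size=(30, 3)) * 40)
        T = RigidTransform.identity((0.0, 0.0, 0.0))
        s = scales_from_physical_shift(T, pts, parameterization="euler")
        np.testing.assert_allclose(s[3:], 1.0, atol=1e-9)

    def test_points_at_center_floor_rotation_scales(self):
        c = np.array([3.0, -1.0, 2.0])
        pts = SamplePointSet(np.tile(c, (5, 1)))
        s = scales_from_physical_shift(RigidTransform.identity(c), pts,
                                       parameterization="euler")
        np.testing.assert_allclose(s[:3], 1.0)

    def test_euler_rotation_scale_matches_small_angle_formula(self):
        R = 50.0
        pts = SamplePointSet(np.array([[R, 0.0, 0.0], [-R, 0.0, 0.0]]))
        s = scales_from_physical_shift(RigidTransform.identity((0, 0, 0)), pts,
                                       parameterization="euler")
        # rotation about y or z displaces a point at radius R by ~R*delta
        np.testing.assert_allclose(s[1], R ** 2, rtol=1e-4)
        np.testing.assert_allclose(s[2], R ** 2, rtol=1e-4)


class TestPowell:
    def test_recovers_quadratic_minimum(self):
        a = np.array([1.0, -2.0, 3.0, 0.5])
        D = np.diag([1.0, 10.0, 0.1, 5.0])
        f = lambda x: float((x - a) @ D @ (x - a))
        x, fval = powell_optimize(f, np.zeros(4))
        assert np.abs(x - a).max() < 1e-6 and fval < 1e-10

    def test_no_increase_from_a_minimizer(self):
        f = lambda x: float(x @ x)
        x, fval = powell_optimize(f, np.zeros(3))
        assert fval <= 1e-15 and np.abs(x).max() < 1e-6

    def test_rosenbrock_matches_reference_optimizer(self):
        from scipy.optimize import fmin_powell, rosen

        f = lambda x: float(rosen(x))
        x, fval = powell_optimize(f, np.array([-1.2, 1.0]),
                                  max_iterations=200)
        assert fval < 1e-6
        ref = fmin_powell(f, np.array([-1.2, 1.0]), disp=False)
        assert np.abs(x - ref).max() < 1e-3

    def test_scales_change_search_space_not_solution(self):
        a = np.array([2.0, -1.0])
        f = lambda x: float((x - a) @ (x - a))
        x, _ = powell_optimize(f, np.zeros(2), scales=np.array([100.0, 1.0]))
        assert np.abs(x - a).max() < 1e-6

    def test_non_finite_objective_aborts(self):
        f = lambda x: float("nan")
        with pytest.raises(OptimizationError):
            powell_optimize(f, np.zeros(2))


class TestGradientDescent:
    def test_monotone_decreasing_on_quadratic_bowl(self):
        trace = []
        f = lambda x: float(x @ x)
        x, _ = gradient_descent_optimize(f, np.array([5.0, -3.0]),
                                         learning_rate=0.1, iterations=200,
                                         callback=trace.append)
        assert np.abs(x).max() < 1e-3
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_immediate_convergence_at_minimum(self):
        f = lambda x: float(x @ x)
        x, fval = gradient_descent_optimize(f, np.zeros(2), iterations=50)
        assert fval < 1e-12

    def test_closed_form_iterates_on_1d_quadratic(self):
        # x_{k+1} = x_k - lr * f'(x_k) = 0.8 x_k for f = x^2, lr = 0.1
        trace = []
        gradient_descent_optimize(lambda x: float(x[0] ** 2), np.array([1.0]),
                                  learning_rate=0.1, iterations=5,
                                  convergence_window=100,
                                  callback=trace.append)
        expect = [(0.8 ** k) ** 2 for k in range(6)]
        np.testing.assert_allclose(trace, expect, rtol=1e-6)

    def test_divergence_aborts_with_diagnostic(self):
        f = lambda x: float(x @ x)
        with pytest.raises(OptimizationError):
            gradient_descent_optimize(f, np.array([1.0, 1.0]),
                                      learning_rate=1.5, iterations=100)

    def test_step_cap_bounds_each_update(self):
        path = [np.array([10.0])]
        def f(x):
            path.append(x.copy())
            return float(x[0] ** 2)
        gradient_descent_optimize(f, np.array([10.0]), learning_rate=10.0,
                                  iterations=10, max_step=0.5,
                                  convergence_window=100, grad_h=1e-6)
        # consecutive accepted iterates move at most the cap (+ fd probes)
        big = [p for p in path if abs(p[0]) > 1]
        assert max(abs(np.diff([p[0] for p in big]))) <= 0.5 + 1e-3


class TestRegisterDriver:
    @pytest.fixture(scope="class")
    def bone_pair_small(self):
        pair = generate(single_bone_spec(seed=2, noise_sd=10.0))
        fixed = pair.pre
        mask = bone_mask(pair.pre_labels)
        return fixed, mask

    def test_self_registration_stays_at_identity(self, bone_pair_small):
        fixed, mask = bone_pair_small
        from bonereg.morphology import dilate_slicewise

        T, report = register(fixed, fixed, dilate_slicewise(mask, 4), INITIAL)
        c = mask.centroid_world()
        assert np.linalg.norm(T.apply(c) - c) < 0.1
        assert report.final_metric < 1.0

    def test_translation_recovery(self):
        spec = single_bone_spec(seed=3, noise_sd=10.0)
        pair_fixed = generate(spec)
        motion = RigidTransform(translation=np.array([5.0, -3.0, 2.0]),
                                center=np.array([21.0, 21.0, 60.0]))
        pair_moved = generate(single_bone_spec(seed=3, motion=motion,
                                               noise_sd=10.0))
        from bonereg.morphology import dilate_slicewise

        mask = bone_mask(pair_fixed.pre_labels)
        T, _ = register(pair_fixed.pre, pair_moved.post,
                        dilate_slicewise(mask, 4), INITIAL)
        # a capsule is rotationally symmetric about its axis, so compare the
        # observable action: displacement of axis points and axis direction
        axis_pts = np.array([[21.0, 21.0, z] for z in (30.0, 60.0, 90.0)])
        err = np.linalg.norm(T.apply(axis_pts) - motion.apply(axis_pts), axis=1)
        assert err.max() < 0.45  # 0.5 * min spacing
        zhat = np.array([0.0, 0.0, 1.0])
        cos = T.rotation.apply(zhat) @ motion.rotation.apply(zhat)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.2

    def test_rotation_recovery_on_asymmetric_bone(self):
        # horizontal capsule: a rotation about the axial (z) axis moves its
        # long axis and is therefore observable
        spec = single_bone_spec(seed=4, noise_sd=10.0, axis="x")
        fixed_pair = generate(spec)
        motion = RigidTransform(Rotation.from_euler("z", np.radians(5.0)),
                                np.zeros(3), np.array([54.0, 32.0, 45.0]))
        moved = generate(single_bone_spec(seed=4, motion=motion, noise_sd=10.0,
                                          axis="x"))
        from bonereg.morphology import dilate_slicewise

        mask = bone_mask(fixed_pair.pre_labels)
        T, report = register(fixed_pair.pre, moved.post,
                             dilate_slicewise(mask, 4), INITIAL)
        # observable rotation: how the recovered map turns the bone's long
        # axis (twist about the capsule's own axis is a symmetry)
        xhat = np.array([1.0, 0.0, 0.0])
        cos = T.rotation.apply(xhat) @ motion.rotation.apply(xhat)
        assert np.degrees(np.arccos(np.clip(cos, -1, 1))) < 0.2
        axis_pts = np.array([[x, 32.0, 45.0] for x in (15.0, 54.0, 93.0)])
        err = np.linalg.norm(T.apply(axis_pts) - motion.apply(axis_pts), axis=1)
        assert err.max() < 0.45
        first = report.levels[0]["trace"][0]
        assert report.final_metric < first  # and hugely reduced overall
        assert report.levels[0]["trace"][-1] < first / 100.0

    def test_deterministic_under_seed(self, bone_pair_small):
        fixed, mask = bone_pair_small
        from bonereg.morphology import dilate_slicewise
        from dataclasses import replace

        pair = generate(single_bone_spec(
            seed=2, noise_sd=10.0,
            motion=RigidTransform(translation=np.array([2.0, 1.0, -3.0]),
                                  center=np.array([21.0, 21.0, 60.0]))))
        cfg = replace(INITIAL, seed=11)
        mm = dilate_slicewise(mask, 4)
        Ta, _ = register(fixed, pair.post, mm, cfg)
        Tb, _ = register(fixed, pair.post, mm, cfg)
        np.testing.assert_array_equal(Ta.parameters("versor"),
                                      Tb.parameters("versor"))

    def test_metric_at_truth_beats_random_perturbations(self):
        spec = single_bone_spec(seed=6, noise_sd=0.0,
                                motion=RigidTransform(
                                    translation=np.array([2.0, -1.0, 3.0]),
                                    center=np.array([21.0, 21.0, 60.0])))
        pair = generate(spec)
        from bonereg.morphology import dilate_slicewise

        mask = dilate_slicewise(bone_mask(pair.pre_labels), 4)
        pts = sample_points(mask, "regular", 0.2, 0)
        gt = pair.transforms["bone"]
        m_gt = mean_squares_metric(pair.pre, pair.post, gt, pts)
        rng = np.random.default_rng(7)
        for _ in range(100):
            delta = RigidTransform(
                Rotation.from_rotvec(rng.normal(size=3) * 0.02),
                rng.normal(size=3) * 2.0, gt.center)
            assert m_gt <= mean_squares_metric(pair.pre, pair.post,
                                               delta.compose(gt), pts)
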