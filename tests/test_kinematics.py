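"""Transform vetting and averaging: outlier rules, component-wise means,
principal rotation axis, origin independence."""

import numpy as np
import pytest

import ossimotion as om
from ossimotion.geometry import random_rigid_transform
from ossimotion.kinematics import transform_parameters


def rot(angle_deg, axis):
    axis = np.asarray(axis, float)
    if angle_deg < 0:
        angle_deg, axis = -angle_deg, -axis
    return om.from_axis_angle(om.AxisAngle(axis / np.linalg.norm(axis), angle_deg))


class TestRejectOutliers:
    def test_five_times_median_discards_the_runaway(self):
        # {1.0, 1.1, 0.9, 1.05, 5.5}: median 1.05, cutoff 5.25 -> 5.5 out;
        # the 2-sigma stage removes nothing among the survivors
        vals = np.array([[1.0], [1.1], [0.9], [1.05], [5.5]])
        mask, warned = om.reject_outliers(vals, om.OutlierPolicy())
        assert mask.tolist() == [True, True, True, True, False]
        assert not warned

    def test_identical_svs_all_pass(self):
        vals = np.ones((6, 7)) * 0.3
        mask, warned = om.reject_outliers(vals)
        assert mask.all() and not warned

    def test_two_svs_pass_with_warning(self):
        vals = np.array([[1.0], [100.0]])
        mask, warned = om.reject_outliers(vals, om.OutlierPolicy(min_survivors=2))
        assert mask.all() and warned

    def test_sigma_rule_catches_moderate_deviant(self):
        # within the 5x-median cutoff but far outside 2 sigma of the rest
        vals = np.array([[1.0], [1.01], [0.99], [1.0], [1.02], [1.9]])
        mask, warned = om.reject_outliers(vals)
        assert mask.tolist() == [True, True, True, True, True, False]

    def test_agreeing_svs_never_discarded(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(-1, 1, 7)
        vals = base + rng.normal(0, 1e-12, (5, 7))
        mask, _ = om.reject_outliers(vals)
        assert mask.all()


class TestAverageTransforms:
    def test_single_transform_unchanged(self):
        T = om.RigidTransform(rot(1.0, (0, 1, 0)), (0.5, 0, 0), origin=(1, 2, 3))
        mean, aa, disp = om.average_transforms([T])
        assert np.allclose(mean.R, T.R) and np.allclose(mean.t, T.t)
        assert np.allclose(disp, 0)

    def test_sign_alignment_prevents_axis_cancellation(self):
        a = np.array([1.0, 0.0, 0.0])
        T1 = om.RigidTransform(rot(1.0, a), np.zeros(3))
        T2 = om.RigidTransform(rot(1.0, -a), np.zeros(3))
        # rotating +1 deg about -a equals -1 deg about a; these are genuinely
        # different rotations whose axis-angle axes are antiparallel
        table = transform_parameters([T1, T2])
        assert np.allclose(np.abs(table[:, 3:6] @ a), 1.0)

    def test_mean_of_noisy_estimates_converges(self):
        rng = np.random.default_rng(4)
        truth = om.RigidTransform(rot(1.2, (0.3, 0.9, 0.1)), (0.8, -0.4, 0.2))
        aa_t = om.to_axis_angle(truth.R)

        def noisy(sd):
            axis = aa_t.axis + rng.normal(0, sd, 3)
            axis /= np.linalg.norm(axis)
            return om.RigidTransform(
                rot(aa_t.angle_deg + rng.normal(0, sd), axis),
                truth.t + rng.normal(0, sd, 3),
            )

        errs = []
        for n in [4, 16, 64]:
            trs = [noisy(0.1) for _ in range(n)]
            mean, _, _ = om.average_transforms(trs)
            errs.append(np.abs(mean.t - truth.t).max())
        # error shrinks roughly like 1/sqrt(N): 16x more samples -> ~4x less
        assert errs[2] < errs[0]

    def test_mismatched_origins_rejected(self):
        T1 = om.RigidTransform(np.eye(3), np.zeros(3), origin=(0, 0, 0))
        T2 = om.RigidTransform(np.eye(3), np.zeros(3), origin=(1, 0, 0))
        with pytest.raises(ValueError, match="origin"):
            om.average_transforms([T1, T2])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            om.average_transforms([])


class TestPrincipalAxis:
    def test_common_axis_recovered_exactly(self):
        u = np.array([0.6, 0.8, 0.0])
        aas = [om.AxisAngle(u, a) for a in [0.5, 1.0, 1.5, 0.8]]
        assert np.allclose(om.principal_rotation_axis(aas), u)

    def test_sign_alternation_over_half_cycles(self):
        u = np.array([0.0, 1.0, 0.0])
        aas = [om.AxisAngle(u, 1.0), om.AxisAngle(-u, 1.0), om.AxisAngle(u, 0.9)]
        out = om.principal_rotation_axis(aas)
        assert np.allclose(np.abs(out), u)

    def test_small_angle_phases_excluded_by_floor(self):
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        aas = [om.AxisAngle(u, 1.0), om.AxisAngle(v, 0.01)]  # v below 10% floor
        assert np.allclose(om.principal_rotation_axis(aas), u)

    def test_all_degenerate_rejected(self):
        aas = [om.AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, degenerate=True)] * 3
        with pytest.raises(ValueError):
            om.principal_rotation_axis(aas)


class TestOriginIndependence:
    def test_displacement_identical_from_any_subvolume_origin(self):
        # the master theorem: after re-expression, any SV's transform moves
        # any absolute point identically (exact on ground-truth transforms)
        rng = np.random.default_rng(11)
        for _ in range(100):
            origin_a = rng.uniform(0, 50, 3)
            T_a = random_rigid_transform(rng, origin=origin_a)
            origin_b = rng.uniform(0, 50, 3)
            T_b = om.reexpress_transform(T_a, origin_b)
            x = rng.uniform(0, 50, 3)
            assert np.allclose(T_a.apply(x), T_b.apply(x), atol=1e-9)


class TestOssicleMotionAssembly:
    def test_consistent_svs_average_to_the_common_truth(self):
        rng = np.random.default_rng(2)
        truth = [om.RigidTransform.identity((10.0, 10, 10), 0)]
        for j in range(1, 6):
            truth.append(
                om.RigidTransform(
                    rot(0.5 * np.sin(2 * np.pi * j / 6), (0, 1, 0)),
                    (0.3 * np.sin(2 * np.pi * j / 6), 0, 0),
                    origin=(10.0, 10, 10),
                    phase=j,
                )
            )
        origins = [np.array([10.0, 10, 10]), np.array([25.0, 12, 8]), np.array([5.0, 30, 14])]
        per_sv = [[om.reexpress_transform(T, o) for T in truth] for o in origins]
        motion = om.ossicle_motion_from_transforms("b", per_sv)
        assert np.allclose(motion.origin, origins[0])
        for j in range(6):
            assert np.allclose(motion.mean_transforms[j].t, truth[j].t, atol=1e-9)
            assert np.allclose(motion.mean_transforms[j].R, truth[j].R, atol=1e-9)
        assert motion.survivor_masks.all()

    def test_contaminated_sv_is_vetoed(self):
        truth = []
        for j in range(6):
            truth.append(
                om.RigidTransform(
                    rot(1.0 * abs(np.sin(2 * np.pi * j / 6)) + 0.2, (0, 1, 0)),
                    (0.5, 0.1, 0.0),
                    origin=(0.0, 0, 0),
                    phase=j,
                )
            )
        good = [list(truth) for _ in range(4)]
        bad = [
            om.RigidTransform(rot(30.0, (1, 0, 0)), (20.0, 0, 0), origin=(0.0, 0, 0), phase=j)
            for j in range(6)
        ]
        motion = om.ossicle_motion_from_transforms("b", good + [bad])
        assert not motion.survivor_masks[1:, 4].any()
        for j in range(1, 6):
            assert np.allclose(motion.mean_transforms[j].t, truth[j].t, atol=1e-9)
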