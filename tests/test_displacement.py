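"""ROI displacement traces, signed norms, constrained sine fits, noise floor."""

import numpy as np
import pytest

import ossimotion as om
from .conftest import circular_distance


def rot(angle_deg, axis):
    axis = np.asarray(axis, float)
    if angle_deg < 0:
        angle_deg, axis = -angle_deg, -axis
    return om.from_axis_angle(om.AxisAngle(axis / np.linalg.norm(axis), angle_deg))


def motion_from_transforms(transforms, label="b"):
    n = len(transforms)
    return om.OssicleMotion(
        ossicle_label=label,
        origin=transforms[0].origin,
        mean_transforms=transforms,
        mean_axis_angles=[om.to_axis_angle(T.R) for T in transforms],
        survivor_masks=np.ones((n, 1), dtype=bool),
        dispersions=np.zeros((n, 7)),
        principal_axis=None,
    )


def sinusoidal_translation_motion(amp_vox, n_phases=10, origin=(0.0, 0, 0)):
    transforms = []
    for j in range(n_phases):
        t = np.asarray(amp_vox, float) * np.sin(2 * np.pi * j / n_phases)
        transforms.append(om.RigidTransform(np.eye(3), t, origin=origin, phase=j))
    return motion_from_transforms(transforms)


TIMES = om.phase_times_ms(10, 128.0)


class TestDisplacePoints:
    def test_identity_motion_gives_zero_trace(self):
        motion = motion_from_transforms(
            [om.RigidTransform.identity((0.0, 0, 0), j) for j in range(10)]
        )
        roi = om.ROIPointSet("r", "b", np.array([[5.0, 6.0, 7.0]]))
        trace = om.displace_points(motion, roi)
        assert np.allclose(trace.vectors_um, 0.0)
        assert np.allclose(trace.norms_um, 0.0)

    def test_pure_translation_converts_voxels_to_micrometres(self):
        motion = sinusoidal_translation_motion((1.0, 0, 0))
        roi = om.ROIPointSet(
            "r", "b", np.array([[3.0, 4, 5], [10.0, 2, 8]]), voxel_size_um=2.75
        )
        trace = om.displace_points(motion, roi)
        expected = 2.75 * np.sin(2 * np.pi * np.arange(10) / 10)
        assert np.allclose(trace.vectors_um[:, 0], expected, atol=1e-12)
        assert np.allclose(trace.norms_um, np.abs(expected), atol=1e-12)
        assert np.allclose(trace.point_sd_um, 0.0)  # same motion at every point

    def test_lever_behavior_point_on_axis_stays_still(self):
        # rotation about an axis through one ROI point: that point barely
        # moves while distal points sweep an arc
        origin = np.array([10.0, 10.0, 10.0])
        transforms = [
            om.RigidTransform(
                rot(1.0 * np.sin(2 * np.pi * j / 10), (0, 0, 1)), np.zeros(3),
                origin=origin, phase=j,
            )
            for j in range(10)
        ]
        motion = motion_from_transforms(transforms)
        on_axis = om.displace_points(
            motion, om.ROIPointSet("on", "b", origin[None, :])
        )
        distal = om.displace_points(
            motion, om.ROIPointSet("far", "b", np.array([[40.0, 10.0, 10.0]]))
        )
        assert np.allclose(on_axis.norms_um, 0.0, atol=1e-9)
        assert distal.norms_um.max() > 1.0

    def test_ossicle_label_mismatch_rejected(self):
        motion = sinusoidal_translation_motion((1.0, 0, 0))
        roi = om.ROIPointSet("r", "other", np.array([[0.0, 0, 0]]))
        with pytest.raises(ValueError, match="belongs to"):
            om.displace_points(motion, roi)


class TestSignedNorms:
    def test_collinear_sinusoid_gives_clean_signed_sine(self):
        motion = sinusoidal_translation_motion((2.0, 0, 0))
        trace = om.displace_points(motion, om.ROIPointSet("r", "b", np.zeros((1, 3))))
        D = om.signed_norms(trace)
        expected = 2.0 * 2.75 * np.sin(2 * np.pi * np.arange(10) / 10)
        assert np.allclose(D, expected, atol=1e-9)

    def test_all_zero_trace_stays_zero(self):
        motion = motion_from_transforms(
            [om.RigidTransform.identity((0.0, 0, 0), j) for j in range(10)]
        )
        trace = om.displace_points(motion, om.ROIPointSet("r", "b", np.zeros((1, 3))))
        assert np.allclose(om.signed_norms(trace), 0.0)

    def test_reference_flip_inverts_signs_and_shifts_phase_half_cycle(self):
        motion = sinusoidal_translation_motion((2.0, 0.5, 0))
        trace = om.displace_points(motion, om.ROIPointSet("r", "b", np.zeros((1, 3))))
        u = np.array([2.0, 0.5, 0.0])
        D_pos = om.signed_norms(trace, reference=u)
        D_neg = om.signed_norms(trace, reference=-u)
        assert np.allclose(D_pos, -D_neg)
        f_pos = om.fit_sine(D_pos, TIMES, 128.0)
        f_neg = om.fit_sine(D_neg, TIMES, 128.0)
        assert np.isclose(f_pos.A_um, f_neg.A_um)
        assert np.isclose(circular_distance(f_pos.phi_cycles, f_neg.phi_cycles), 0.5)
        assert np.isclose(f_pos.R2, f_neg.R2)

    def test_figure_eight_lowers_goodness_of_fit(self):
        # a secondary orthogonal lobe at doubled frequency (the stapes-like
        # figure-8) leaves the primary sine dominant but lowers R^2
        j = np.arange(10)
        primary = 2.0 * np.sin(2 * np.pi * j / 10)
        secondary = 1.2 * np.sin(4 * np.pi * j / 10)
        transforms = [
            om.RigidTransform(np.eye(3), (primary[k], secondary[k], 0.0), phase=k)
            for k in j
        ]
        trace8 = om.displace_points(
            motion_from_transforms(transforms), om.ROIPointSet("r", "b", np.zeros((1, 3)))
        )
        fit8 = om.fit_sine(om.signed_norms(trace8), TIMES, 128.0)
        clean = om.displace_points(
            sinusoidal_translation_motion((2.0, 0, 0)),
            om.ROIPointSet("r", "b", np.zeros((1, 3))),
        )
        fit_clean = om.fit_sine(om.signed_norms(clean), TIMES, 128.0)
        assert fit_clean.R2 > 0.999999
        assert fit8.R2 < fit_clean.R2 - 0.005
        assert np.isclose(fit8.A_um / 2.75, 2.0, rtol=0.25)  # primary still dominates


class TestFitSine:
    def test_noiseless_samples_recovered_exactly(self):
        D = 2.0 * np.sin(2 * np.pi * (128.0 * TIMES / 1000.0 + 0.25))
        fit = om.fit_sine(D, TIMES, 128.0)
        assert abs(fit.A_um - 2.0) < 1e-9
        assert abs(fit.phi_cycles - 0.25) < 1e-9
        assert abs(fit.R2 - 1.0) < 1e-9

    def test_zero_series_fits_with_unit_r2_by_convention(self):
        fit = om.fit_sine(np.zeros(10), TIMES, 128.0)
        assert fit.A_um == 0.0 and fit.R2 == 1.0

    def test_amplitude_unbiased_under_noise_monte_carlo(self):
        rng = np.random.default_rng(6)
        A = 3.0
        errs = []
        for _ in range(500):
            D = A * np.sin(2 * np.pi * (128.0 * TIMES / 1000.0 + 0.1))
            D = D + rng.normal(0, 0.1 * A, size=D.size)
            errs.append(om.fit_sine(D, TIMES, 128.0).A_um - A)
        assert abs(np.mean(errs)) < 0.05 * A

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            om.fit_sine(np.array([1.0, 2.0]), TIMES[:2], 128.0)


class TestAmplitudeRatio:
    def test_arithmetic(self):
        hi = om.SineFit(1.8, 0.0, 128.0, 1.0)
        lo = om.SineFit(1.2, 0.0, 128.0, 1.0)
        assert np.isclose(om.amplitude_ratio(hi, lo), 1.5)
        assert om.amplitude_ratio(lo, lo) == 1.0

    def test_zero_denominator_rejected(self):
        hi = om.SineFit(1.0, 0.0, 128.0, 1.0)
        lo = om.SineFit(0.0, 0.0, 128.0, 1.0)
        with pytest.raises(ValueError):
            om.amplitude_ratio(hi, lo)


class TestLeverArm:
    def test_amplitude_proportional_to_distance_from_axis(self):
        # pure rotation: fitted amplitude vs distance from the axis is a
        # straight line through the origin (R^2 > 0.999 on exact transforms)
        origin = np.zeros(3)
        transforms = [
            om.RigidTransform(
                rot(1.0 * np.sin(2 * np.pi * j / 10), (0, 0, 1)), np.zeros(3),
                origin=origin, phase=j,
            )
            for j in range(10)
        ]
        motion = motion_from_transforms(transforms)
        dists = np.array([5.0, 10.0, 20.0, 40.0, 60.0])
        amps = []
        for d in dists:
            roi = om.ROIPointSet("r", "b", np.array([[d, 0.0, 0.0]]))
            D = om.signed_norms(om.displace_points(motion, roi))
            amps.append(om.fit_sine(D, TIMES, 128.0).A_um)
        amps = np.array(amps)
        slope = (dists * amps).sum() / (dists * dists).sum()
        ss_res = ((amps - slope * dists) ** 2).sum()
        ss_tot = ((amps - amps.mean()) ** 2).sum()
        assert 1.0 - ss_res / ss_tot > 0.999


class TestNoiseFloor:
    def test_identity_motion_passes_with_zero_maxima(self):
        motion = motion_from_transforms(
            [om.RigidTransform.identity((0.0, 0, 0), j) for j in range(10)]
        )
        report = om.noise_floor(motion, np.array([[10.0, 0, 0]]))
        assert report.passed
        assert report.max_point_displacement_um == 0.0

    def test_injected_drift_fails_naming_the_translation_bound(self):
        transforms = [om.RigidTransform.identity((0.0, 0, 0), 0)] + [
            om.RigidTransform(np.eye(3), (1.0, 0, 0), phase=j) for j in range(1, 10)
        ]
        report = om.noise_floor(motion_from_transforms(transforms), np.zeros((1, 3)))
        assert not report.passed
        assert any("translation" in f for f in report.failures)
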