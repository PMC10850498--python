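"""Shared fixtures: phantoms and pipeline runs reused across test modules.

Heavy artifacts (rendered phase series, registration sweeps) are session
scoped so each is computed once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

import ossimotion as om


def stock_subvolumes() -> list[om.SubVolumeSpec]:
    """Three sub-volumes per body of the stock three-ossicle phantom (96 grid)."""
    return [
        om.SubVolumeSpec("malleus", (30, 48, 32), (13, 13, 9)),
        om.SubVolumeSpec("malleus", (30, 48, 46), (13, 13, 9)),
        om.SubVolumeSpec("malleus", (30, 48, 60), (13, 13, 7)),
        om.SubVolumeSpec("incus", (62, 48, 42), (13, 11, 9)),
        om.SubVolumeSpec("incus", (62, 48, 56), (13, 11, 10)),
        om.SubVolumeSpec("incus", (66, 48, 50), (9, 11, 13)),
        om.SubVolumeSpec("stapes", (48, 24, 60), (13, 11, 10)),
        om.SubVolumeSpec("stapes", (44, 24, 58), (11, 10, 9)),
        om.SubVolumeSpec("stapes", (52, 26, 62), (9, 9, 8)),
    ]


def ncc_params() -> om.RegistrationParams:
    """Normalized cross-correlation: the well-conditioned metric for
    mono-modal phantom data."""
    return om.RegistrationParams(metric="normalized_cross_correlation")


def ground_truth_motion(gt: om.GroundTruth, label: str, origin) -> om.OssicleMotion:
    """Wrap a body's ground-truth transforms as an OssicleMotion at ``origin``
    so displacement tooling runs identically on truth and estimates."""
    transforms = [om.reexpress_transform(T, origin) for T in gt.transforms[label]]
    aas = [om.to_axis_angle(T.R) for T in transforms]
    n = len(transforms)
    return om.OssicleMotion(
        ossicle_label=label,
        origin=np.asarray(origin, float),
        mean_transforms=transforms,
        mean_axis_angles=aas,
        survivor_masks=np.ones((n, 1), dtype=bool),
        dispersions=np.zeros((n, 7)),
        principal_axis=None,
    )


def circular_distance(phi_a: float, phi_b: float) -> float:
    d = abs(phi_a - phi_b) % 1.0
    return min(d, 1.0 - d)


@pytest.fixture(scope="session")
def small_textured_phantom():
    """One textured ellipsoid, 10 phases, mixed rotation + translation,
    noiseless — the workhorse for registration unit tests (64-voxel grid)."""
    body = om.BodySpec(
        "body",
        "ellipsoid",
        center=(32, 32, 32),
        size=(17, 14, 15),
        texture_seed=5,
        motion_axis=(0.0, 1.0, 0.0),
        angle_amplitude_deg=1.5,
        translation_amplitude=(1.25, -0.5, 0.75),
    )
    spec = om.PhantomSpec(grid_shape=(64, 64, 64), n_phases=10, bodies=(body,), seed=5)
    series, gt = om.generate_phase_volumes(spec)
    return spec, series, gt


@pytest.fixture(scope="session")
def three_body_snr20():
    """The stock three-ossicle phantom at SNR 20 (body intensity 1.0, noise
    sigma 0.05), registered with three SVs per body — the end-to-end
    recovery workhorse."""
    spec = om.default_three_body_spec(grid=96, noise_sigma=0.05, seed=3)
    series, gt = om.generate_phase_volumes(spec)
    transforms = om.register_series(series, stock_subvolumes(), ncc_params())
    motions = {
        label: om.ossicle_motion_from_transforms(label, rows)
        for label, rows in transforms.items()
    }
    return spec, gt, motions
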