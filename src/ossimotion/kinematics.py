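"""From per-sub-volume transforms to one mean rigid motion per ossicle.

Under the rigid-body assumption every sub-volume (SV) of an ossicle must
report the same motion once re-expressed from a common origin.  This module
re-expresses each SV transform at the global origin (the center of the
first SV listed for the ossicle), vets the seven per-SV parameters (three
translation components, three rotation-axis components, one rotation angle)
with a 5x-median and a 2-sigma discard rule, averages the survivors
component-wise, and derives the principal rotation axis over the cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    AxisAngle,
    RigidTransform,
    amplify_transform,
    axis_angle_between,
    from_axis_angle,
    reexpress_transform,
    to_axis_angle,
)

__all__ = [
    "OutlierPolicy",
    "OssicleMotion",
    "to_axis_angle",
    "from_axis_angle",
    "reexpress_transform",
    "axis_angle_between",
    "amplify_transform",
    "transform_parameters",
    "reject_outliers",
    "average_transforms",
    "principal_rotation_axis",
    "ossicle_motion_from_transforms",
]

PARAMETER_NAMES = ("tx", "ty", "tz", "ax", "ay", "az", "angle_deg")


@dataclass(frozen=True)
class OutlierPolicy:
    """Discard rules for per-SV transform estimates at one phase.

    ``k_median`` (default 5): an SV whose parameter magnitude exceeds
    ``k_median * |median|`` of that parameter's distribution is discarded —
    the signature of a registration that failed to converge.  ``k_sigma``
    (default 2): among the remainder, an SV deviating from the sample mean
    by more than ``k_sigma`` standard deviations in any parameter is
    discarded.  If fewer than ``min_survivors`` remain, all SVs are kept and
    a warning flag is raised instead.
    """

    k_sigma: float = 2.0
    k_median: float = 5.0
    min_survivors: int = 2
    per_phase: bool = True  # False: an SV discarded anywhere is dropped everywhere

    def __post_init__(self) -> None:
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.k_median <= 1:
            raise ValueError("k_median must exceed 1")


@dataclass
class OssicleMotion:
    """The vetted, averaged motion of one ossicle over the cycle."""

    ossicle_label: str
    origin: np.ndarray  # global origin O_0, (x, y, z) voxels
    mean_transforms: list[RigidTransform]  # one per phase, at origin
    mean_axis_angles: list[AxisAngle]
    survivor_masks: np.ndarray  # (n_phases, n_sv) bool
    dispersions: np.ndarray  # (n_phases, 7) sample std of the parameters
    principal_axis: np.ndarray | None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_phases(self) -> int:
        return len(self.mean_transforms)

    def angle_profile_deg(self) -> np.ndarray:
        return np.array([aa.angle_deg for aa in self.mean_axis_angles])

    def translation_magnitude(self) -> np.ndarray:
        return np.array([np.linalg.norm(T.t) for T in self.mean_transforms])


def transform_parameters(transforms: list[RigidTransform]) -> np.ndarray:
    """The (n_sv, 7) parameter table of transforms sharing one origin:
    translation components, rotation-axis components (sign-aligned to the
    largest-angle member), and rotation angle in degrees."""
    aas = [to_axis_angle(T.R) for T in transforms]
    angles = np.array([aa.angle_deg for aa in aas])
    ref = aas[int(np.argmax(angles))].axis
    rows = []
    for T, aa in zip(transforms, aas):
        axis = aa.axis if np.dot(aa.axis, ref) >= 0 else -aa.axis
        rows.append(np.concatenate([T.t, axis, [aa.angle_deg]]))
    return np.array(rows)


def reject_outliers(params: np.ndarray, policy: OutlierPolicy = OutlierPolicy()) -> tuple[np.ndarray, bool]:
    """Survivor mask over SVs from the two-stage discard rule.

    Stage 1 (5x-median, on the original distribution, absolute values):
    drop SVs with any ``|value| > k_median * |median(values)|`` — magnitudes
    this far out come from non-converged registrations.  Stage 2 (2-sigma,
    on the stage-1 survivors): drop SVs deviating from the survivor mean by
    more than ``k_sigma`` sample standard deviations in any parameter.
    Zero-variance parameters discard nothing.  Returns (mask, warned); if
    fewer than ``min_survivors`` SVs would remain, all pass and
    ``warned=True``.
    """
    params = np.asarray(params, dtype=float)
    if params.ndim != 2:
        raise ValueError("parameter table must be 2D (n_sv, n_params)")
    n_sv = params.shape[0]
    if n_sv < 3:
        # with two estimates neither a dispersion nor a robust center is
        # meaningful; keep both and flag it
        return np.ones(n_sv, dtype=bool), n_sv >= 2

    med = np.median(params, axis=0)
    cutoff = policy.k_median * np.abs(med)
    with np.errstate(invalid="ignore"):
        stage1 = ~np.any(np.abs(params) > cutoff, axis=1)

    mask = stage1.copy()
    if mask.sum() >= 2:
        surv = params[mask]
        mu = surv.mean(axis=0)
        sd = surv.std(axis=0, ddof=1)
        ok = sd > 0
        if ok.any():
            dev = np.abs(params[:, ok] - mu[ok]) > policy.k_sigma * sd[ok]
            mask &= ~np.any(dev, axis=1)

    if mask.sum() < policy.min_survivors:
        return np.ones(n_sv, dtype=bool), True
    return mask, False


def average_transforms(
    transforms: list[RigidTransform],
) -> tuple[RigidTransform, AxisAngle, np.ndarray]:
    """Component-wise mean of rigid transforms sharing one origin.

    Translations average component-wise; rotation axes are sign-aligned to
    the largest-angle member before the component-wise mean and
    renormalization; the angle averages as a scalar; the mean rotation
    matrix is rebuilt from the mean axis-angle.  Returns the mean transform,
    the mean axis-angle and the (7,) per-parameter sample standard
    deviations (the error bars of angle/translation-vs-phase plots).
    """
    if len(transforms) == 0:
        raise ValueError("cannot average an empty set of transforms")
    origin = transforms[0].origin
    for T in transforms:
        if not np.allclose(T.origin, origin, atol=1e-9):
            raise ValueError("all transforms must share one origin before averaging")
    phase = transforms[0].phase
    if len(transforms) == 1:
        T = transforms[0]
        aa = to_axis_angle(T.R)
        return T, aa, np.zeros(7)

    table = transform_parameters(transforms)
    mean = table.mean(axis=0)
    disp = table.std(axis=0, ddof=1)
    t_mean = mean[:3]
    axis_mean = mean[3:6]
    angle_mean = float(mean[6])
    n = np.linalg.norm(axis_mean)
    if angle_mean < 1e-6 or n < 1e-12:
        aa = AxisAngle(np.array([0.0, 0.0, 1.0]), max(angle_mean, 0.0), degenerate=True)
    else:
        aa = AxisAngle(axis_mean / n, angle_mean)
    R = from_axis_angle(aa)
    return RigidTransform(R, t_mean, origin, phase=phase), aa, disp


def principal_rotation_axis(
    axis_angles: list[AxisAngle], angle_floor: float = 0.1
) -> np.ndarray:
    """Angle-weighted mean rotation axis over the cycle.

    Phases whose angle is below ``angle_floor`` of the cycle maximum (or
    degenerate) are excluded — near the zero crossings of the motion the
    axis direction is pure noise.  Remaining axes are sign-aligned to the
    axis at the phase of maximum angle, weighted by their angle, averaged
    and renormalized.
    """
    angles = np.array([aa.angle_deg for aa in axis_angles])
    usable = [
        (aa, a)
        for aa, a in zip(axis_angles, angles)
        if not aa.degenerate and a >= angle_floor * angles.max() and a > 0
    ]
    if not usable:
        raise ValueError("all phases are rotationally degenerate; no principal axis")
    ref = max(usable, key=lambda p: p[1])[0].axis
    acc = np.zeros(3)
    for aa, a in usable:
        axis = aa.axis if np.dot(aa.axis, ref) >= 0 else -aa.axis
        acc += a * axis
    n = np.linalg.norm(acc)
    if n < 1e-12:
        raise ValueError("axis average vanished; no principal direction")
    return acc / n


def ossicle_motion_from_transforms(
    ossicle_label: str,
    per_sv_transforms: list[list[RigidTransform]],
    policy: OutlierPolicy = OutlierPolicy(),
    angle_floor: float = 0.1,
) -> OssicleMotion:
    """Full averaging stage for one ossicle.

    ``per_sv_transforms[i][j]`` is SV i's transform at phase j (any origin;
    each is re-expressed at the global origin O_0 = the first SV's rotation
    center).  Per phase: outlier rejection, then component-wise averaging of
    the survivors; finally the principal rotation axis of the mean motion.
    """
    n_sv = len(per_sv_transforms)
    if n_sv == 0:
        raise ValueError("need at least one sub-volume")
    n_phases = len(per_sv_transforms[0])
    if any(len(row) != n_phases for row in per_sv_transforms):
        raise ValueError("all SVs must cover the same phases")
    origin = per_sv_transforms[0][0].origin

    reexp = [
        [reexpress_transform(T, origin) for T in row] for row in per_sv_transforms
    ]

    warnings: list[str] = []
    masks = np.ones((n_phases, n_sv), dtype=bool)
    if n_sv >= 2:
        for j in range(1, n_phases):  # phase 0 is the exact identity reference
            table = transform_parameters([row[j] for row in reexp])
            mask, warned = reject_outliers(table, policy)
            masks[j] = mask
            if warned:
                warnings.append(f"phase {j}: outlier rule left < {policy.min_survivors} SVs; kept all")
        if not policy.per_phase:
            keep = masks[1:].all(axis=0)
            if keep.sum() >= policy.min_survivors:
                masks[:] = keep
            else:
                warnings.append("whole-SV policy left too few SVs; kept all")
                masks[:] = True

    mean_transforms: list[RigidTransform] = []
    mean_aas: list[AxisAngle] = []
    disps = np.zeros((n_phases, 7))
    for j in range(n_phases):
        survivors = [reexp[i][j] for i in range(n_sv) if masks[j, i]]
        T, aa, disp = average_transforms(survivors)
        mean_transforms.append(RigidTransform(T.R, T.t, origin, phase=j))
        mean_aas.append(aa)
        disps[j] = disp

    try:
        principal = principal_rotation_axis(mean_aas, angle_floor)
    except ValueError:
        principal = None
        warnings.append("no principal rotation axis (all phases degenerate)")

    return OssicleMotion(
        ossicle_label=ossicle_label,
        origin=origin,
        mean_transforms=mean_transforms,
        mean_axis_angles=mean_aas,
        survivor_masks=masks,
        dispersions=disps,
        principal_axis=principal,
        warnings=warnings,
    )
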