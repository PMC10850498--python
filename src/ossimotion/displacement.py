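"""ROI displacement traces, constrained sine fits, and the noise floor.

Anatomical points (umbo, lenticular process, stapes footplate, ...) are
carried through the per-phase mean rigid transforms of their ossicle; the
per-phase displacement norms get a sign from their projection on the
dominant displacement direction and are fitted with the constrained sine

    D(t) = A * sin(2*pi*(f*t + phi))

where the frequency f is the acoustic stimulation frequency and is NOT
fitted — only the amplitude A and the cycle-fraction phase shift phi are
free.  Because the model is linear in (A*cos(2*pi*phi), A*sin(2*pi*phi))
the fit is a closed-form least-squares solve: deterministic, global, no
initialization issues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import to_axis_angle
from .kinematics import OssicleMotion

__all__ = [
    "ROIPointSet",
    "DisplacementTrace",
    "SineFit",
    "NoiseFloorReport",
    "displace_points",
    "signed_norms",
    "fit_sine",
    "amplitude_ratio",
    "noise_floor",
]


@dataclass(frozen=True)
class ROIPointSet:
    """Tracked anatomical points of one ossicle, absolute voxel coords."""

    roi_label: str
    ossicle_label: str
    points: np.ndarray  # (n_points, 3) in (x, y, z)
    voxel_size_um: float = 2.75

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.shape[0] < 1 or pts.shape[1] != 3:
            raise ValueError("need at least one 3D point")
        object.__setattr__(self, "points", pts)


@dataclass
class DisplacementTrace:
    """Per-phase ROI displacement, in micrometres.

    ``vectors_um[j]`` is the point-averaged displacement vector at phase j
    (phase 0 is the reference, so it is exactly zero); ``per_point_um`` keeps
    the (n_phases, n_points) per-point norms whose spread quantifies the
    sensitivity to the manual point selection.
    """

    roi_label: str
    ossicle_label: str
    vectors_um: np.ndarray  # (n_phases, 3)
    norms_um: np.ndarray  # (n_phases,) unsigned
    per_point_um: np.ndarray  # (n_phases, n_points) unsigned norms
    point_sd_um: np.ndarray  # (n_phases,)
    times_ms: np.ndarray | None = None

    @property
    def n_phases(self) -> int:
        return int(self.vectors_um.shape[0])


@dataclass(frozen=True)
class SineFit:
    """Constrained-sine fit result: amplitude (um), phase shift (cycle
    fraction in [0, 1)), the fixed frequency, and R^2."""

    A_um: float
    phi_cycles: float
    f_hz: float
    R2: float

    def __post_init__(self) -> None:
        if self.A_um < 0:
            raise ValueError("amplitude must be non-negative")
        if not 0.0 <= self.phi_cycles < 1.0:
            raise ValueError("phase shift must lie in [0, 1)")

    @property
    def peak_to_peak_um(self) -> float:
        return 2.0 * self.A_um


@dataclass
class NoiseFloorReport:
    """Apparent motion of a confirmed-static region, bounding the smallest
    trustworthy displacement downstream."""

    max_translation_um: float
    max_rotation_deg: float
    max_point_displacement_um: float
    bound_translation_um: float
    bound_rotation_deg: float
    bound_displacement_um: float
    passed: bool
    failures: list[str] = field(default_factory=list)


def displace_points(motion: OssicleMotion, roi: ROIPointSet) -> DisplacementTrace:
    """Track ROI points through the mean per-phase transforms.

    For each point x: d_j = T_j(x) - x (voxels), converted to micrometres;
    the ROI trace is the point-average, with the per-phase standard
    deviation across points recording the selection sensitivity.
    """
    if roi.ossicle_label != motion.ossicle_label:
        raise ValueError(
            f"ROI belongs to {roi.ossicle_label!r}, motion to {motion.ossicle_label!r}"
        )
    n_phases = motion.n_phases
    n_points = roi.points.shape[0]
    vecs = np.zeros((n_phases, 3))
    per_point = np.zeros((n_phases, n_points))
    for j, T in enumerate(motion.mean_transforms):
        d = (T.apply(roi.points) - roi.points) * roi.voxel_size_um
        vecs[j] = d.mean(axis=0)
        per_point[j] = np.linalg.norm(d, axis=1)
    norms = np.linalg.norm(vecs, axis=1)
    sd = per_point.std(axis=1, ddof=1) if n_points > 1 else np.zeros(n_phases)
    return DisplacementTrace(
        roi_label=roi.roi_label,
        ossicle_label=roi.ossicle_label,
        vectors_um=vecs,
        norms_um=norms,
        per_point_um=per_point,
        point_sd_um=sd,
    )


def signed_norms(trace: DisplacementTrace, reference: np.ndarray | None = None) -> np.ndarray:
    """Displacement norms with a direction sign.

    The reference direction u is the unit displacement vector at the phase
    of maximum |d| (overridable); each phase's norm gets the sign of
    ``d_j . u`` (zero projections count positive), so the series crosses
    zero like the underlying oscillation instead of rectifying at it.
    """
    if trace.n_phases < 3:
        raise ValueError("need at least 3 phases for a signed series")
    if reference is None:
        k = int(np.argmax(trace.norms_um))
        if trace.norms_um[k] == 0:
            return trace.norms_um.copy()
        u = trace.vectors_um[k] / trace.norms_um[k]
    else:
        u = np.asarray(reference, dtype=float).reshape(3)
        n = np.linalg.norm(u)
        if n < 1e-12:
            raise ValueError("reference direction must be a nonzero vector")
        u = u / n
    signs = np.where(trace.vectors_um @ u < 0, -1.0, 1.0)
    return signs * trace.norms_um


def fit_sine(D_um: np.ndarray, times_ms: np.ndarray, f_hz: float) -> SineFit:
    """Fit D(t) = A sin(2*pi*(f t + phi)) with f fixed, by linear least
    squares on the sin/cos basis at frequency f.

    With D = a sin(wt) + b cos(wt), A = hypot(a, b) and
    phi = atan2(b, a) / 2*pi (mod 1); the (-A, phi) ambiguity is
    canonicalized to A >= 0 via phi -> phi + 0.5.  R^2 is reported against
    the series mean; an identically-zero series fits exactly (R^2 = 1 by the
    zero-residual convention).
    """
    D = np.asarray(D_um, dtype=float).reshape(-1)
    t = np.asarray(times_ms, dtype=float).reshape(-1) / 1000.0  # -> seconds
    if D.size != t.size:
        raise ValueError("series and times must have equal length")
    if D.size < 3:
        raise ValueError("need at least 3 phases to fit the sine")
    if f_hz <= 0:
        raise ValueError("frequency must be positive")
    w = 2.0 * np.pi * f_hz
    X = np.column_stack([np.sin(w * t), np.cos(w * t)])
    (a, b), *_ = np.linalg.lstsq(X, D, rcond=None)
    A = float(np.hypot(a, b))
    phi = float(np.arctan2(b, a) / (2.0 * np.pi)) % 1.0
    model = X @ np.array([a, b])
    ss_res = float(np.sum((D - model) ** 2))
    ss_tot = float(np.sum((D - D.mean()) ** 2))
    if ss_tot == 0.0:
        R2 = 1.0
    else:
        R2 = 1.0 - ss_res / ss_tot
    if A == 0.0:
        phi = 0.0
    return SineFit(A_um=A, phi_cycles=phi, f_hz=float(f_hz), R2=R2)


def amplitude_ratio(fit_high: SineFit, fit_low: SineFit) -> float:
    """Amplitude ratio between two stimulation conditions (high / low)."""
    if fit_low.A_um == 0:
        raise ValueError("low-condition amplitude is zero; ratio undefined")
    if fit_high.A_um <= 0 or fit_low.A_um < 0:
        raise ValueError("amplitudes must be positive")
    return fit_high.A_um / fit_low.A_um


def noise_floor(
    motion: OssicleMotion,
    probe_points: np.ndarray,
    voxel_size_um: float = 2.75,
    bound_translation_um: float = 0.2,
    bound_rotation_deg: float = 0.002,
    bound_displacement_um: float = 0.3,
) -> NoiseFloorReport:
    """Run the motion of a confirmed-STATIC region through the same pipeline
    and report its apparent maxima.

    Any apparent translation, rotation or induced point displacement of a
    region known to be still measures the method's noise; downstream
    amplitudes below these maxima are not trustworthy.  Defaults for the
    bounds correspond to the sub-voxel regime (0.2 um translation, 0.002 deg
    rotation, 0.3 um displacement at 2.75 um voxels).
    """
    pts = np.atleast_2d(np.asarray(probe_points, dtype=float))
    max_t = 0.0
    max_rot = 0.0
    max_disp = 0.0
    for T in motion.mean_transforms:
        max_t = max(max_t, float(np.linalg.norm(T.t)) * voxel_size_um)
        max_rot = max(max_rot, to_axis_angle(T.R).angle_deg)
        d = np.linalg.norm(T.apply(pts) - pts, axis=1).max() * voxel_size_um
        max_disp = max(max_disp, float(d))
    failures = []
    if max_t > bound_translation_um:
        failures.append(
            f"translation magnitude {max_t:.4f} um exceeds bound {bound_translation_um} um"
        )
    if max_rot > bound_rotation_deg:
        failures.append(
            f"rotation angle {max_rot:.5f} deg exceeds bound {bound_rotation_deg} deg"
        )
    if max_disp > bound_displacement_um:
        failures.append(
            f"point displacement {max_disp:.4f} um exceeds bound {bound_displacement_um} um"
        )
    return NoiseFloorReport(
        max_translation_um=max_t,
        max_rotation_deg=max_rot,
        max_point_displacement_um=max_disp,
        bound_translation_um=bound_translation_um,
        bound_rotation_deg=bound_rotation_deg,
        bound_displacement_um=bound_displacement_um,
        passed=not failures,
        failures=failures,
    )
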