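"""Rigid-transform and axis-angle algebra.

All 3-vectors are in (x, y, z) order and voxel units unless stated otherwise.
A :class:`RigidTransform` maps a point ``x`` (absolute coordinates) to

    x' = origin + R @ (x - origin) + t

i.e. the rotation acts about ``origin`` (the rotation center) and ``t`` is the
translation expressed *from that origin*.  Re-expressing the same physical
motion from a different origin changes ``t`` but never ``R``:

    t_new = t + (R - I) @ (new_origin - old_origin)

which is the uniqueness-of-affine-transform identity used to bring per
sub-volume transforms into one global frame before averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "to_axis_angle",
    "from_axis_angle",
    "reexpress_transform",
    "axis_angle_between",
    "amplify_transform",
    "random_rigid_transform",
]

#: Rotations below this angle (degrees) are treated as identity for the
#: purpose of axis extraction; the axis is then the (0, 0, 1) convention.
DEGENERATE_ANGLE_DEG = 1e-6

_ORTHO_TOL = 1e-6


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise ValueError(f"rotation matrix must be 3x3, got {R.shape}")
    if not np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL):
        raise ValueError("matrix is not orthonormal (R^T R != I)")
    if not np.isclose(np.linalg.det(R), 1.0, atol=_ORTHO_TOL):
        raise ValueError("matrix is not a proper rotation (det != +1)")
    return R


@dataclass(frozen=True)
class RigidTransform:
    """Rotation + translation about an explicit rotation center.

    Parameters
    ----------
    R : (3, 3) rotation matrix (orthonormal, det +1).
    t : (3,) translation, voxel units, expressed from ``origin``.
    origin : (3,) absolute rotation center, voxel units.
    phase : phase index this transform belongs to (reference phase is 0).
    converged : whether the producing registration converged (True for
        analytic / ground-truth transforms).
    """

    R: np.ndarray
    t: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    phase: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", _check_rotation(self.R))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float).reshape(3))

    @classmethod
    def identity(cls, origin=(0.0, 0.0, 0.0), phase: int = 0) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(origin, float), phase)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map absolute points (N, 3) or (3,) through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        out = (pts - self.origin) @ self.R.T + self.origin + self.t
        return out[0] if np.ndim(points) == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (other applied first), at self.origin."""
        o = reexpress_transform(other, self.origin)
        R = self.R @ o.R
        t = self.R @ o.t + self.t
        return RigidTransform(R, t, self.origin, self.phase, self.converged and other.converged)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R.T @ self.t, self.origin, self.phase, self.converged)

    def is_identity(self, atol: float = 1e-12) -> bool:
        return bool(
            np.allclose(self.R, np.eye(3), atol=atol) and np.allclose(self.t, 0.0, atol=atol)
        )


@dataclass(frozen=True)
class AxisAngle:
    """Euler axis-angle rotation descriptor: unit axis and angle in degrees.

    ``degenerate`` flags angles below the numeric threshold where the axis
    direction is meaningless; such axes are set to the (0, 0, 1) convention.
    """

    axis: np.ndarray
    angle_deg: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float).reshape(3)
        if not self.degenerate and not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
            raise ValueError("axis must be a unit vector")
        if not 0.0 <= self.angle_deg <= 180.0 + 1e-12:
            raise ValueError("angle must lie in [0, 180] degrees")
        object.__setattr__(self, "axis", axis)


def to_axis_angle(R: np.ndarray) -> AxisAngle:
    """Convert a rotation matrix to its Euler axis-angle form.

    The angle is returned in [0, 180] degrees.  Identity (and near-identity)
    rotations get the conventional axis (0, 0, 1) and the degenerate flag.
    The 180-degree case, where the standard skew-symmetric extraction
    vanishes, is handled through the symmetric part of R.
    """
    R = _check_rotation(R)
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    angle_deg = np.degrees(theta)
    if angle_deg < DEGENERATE_ANGLE_DEG:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, degenerate=True)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    sin_theta = np.linalg.norm(w) / 2.0
    if sin_theta > 1e-8:
        axis = w / (2.0 * sin_theta)
        # arccos is ill-conditioned near 0 and pi; atan2 keeps full precision
        theta = np.arctan2(sin_theta, cos_theta)
        return AxisAngle(axis / np.linalg.norm(axis), float(np.degrees(theta)))
    # theta ~ pi: R = 2 a a^T - I
    B = (R + np.eye(3)) / 2.0
    k = int(np.argmax(np.diag(B)))
    axis = B[:, k] / np.sqrt(B[k, k])
    axis /= np.linalg.norm(axis)
    return AxisAngle(axis, float(angle_deg))


def from_axis_angle(aa: AxisAngle) -> np.ndarray:
    """Rodrigues formula: rotation matrix from axis-angle."""
    if aa.degenerate or aa.angle_deg < DEGENERATE_ANGLE_DEG:
        return np.eye(3)
    theta = np.radians(aa.angle_deg)
    a = aa.axis / np.linalg.norm(aa.axis)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(theta) * K + (1.0 - np.cos(theta)) * (K @ K)


def reexpress_transform(T: RigidTransform, new_origin) -> RigidTransform:
    """Re-express a rigid transform from a different rotation center.

    The rotation is unchanged; the translation picks up ``(R - I) @ b`` with
    ``b = new_origin - old_origin``, so the induced mapping of any absolute
    point is identical before and after.
    """
    new_origin = np.asarray(new_origin, dtype=float).reshape(3)
    b = new_origin - T.origin
    t_new = T.t + (T.R - np.eye(3)) @ b
    return RigidTransform(T.R, t_new, new_origin, T.phase, T.converged)


def axis_angle_between(axis_a, axis_b) -> float:
    """Sign-invariant angle between two rotation axes, degrees in [0, 90]."""
    a = np.asarray(axis_a, dtype=float).reshape(3)
    b = np.asarray(axis_b, dtype=float).reshape(3)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("axis must be a nonzero vector")
    cosang = np.clip(abs(np.dot(a / na, b / nb)), 0.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def amplify_transform(T: RigidTransform, k: float) -> RigidTransform:
    """Scale a rigid motion by ``k`` for visualization (axis kept, angle and
    translation multiplied; angle capped at 180 degrees with a warning)."""
    import warnings

    if k <= 0:
        raise ValueError("amplification factor must be positive")
    if k == 1.0:
        return T
    aa = to_axis_angle(T.R)
    angle = aa.angle_deg * k
    if angle > 180.0:
        warnings.warn(f"amplified angle {angle:.2f} deg capped at 180", stacklevel=2)
        angle = 180.0
    R = from_axis_angle(AxisAngle(aa.axis, angle, aa.degenerate))
    return RigidTransform(R, T.t * k, T.origin, T.phase, T.converged)


def random_rigid_transform(
    rng: np.random.Generator,
    max_angle_deg: float = 5.0,
    max_translation: float = 3.0,
    origin=(0.0, 0.0, 0.0),
) -> RigidTransform:
    """Draw a random small rigid transform (uniform axis, uniform angle)."""
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.uniform(-max_translation, max_translation, size=3)
    R = from_axis_angle(AxisAngle(axis, angle))
    return RigidTransform(R, t, np.asarray(origin, float))
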