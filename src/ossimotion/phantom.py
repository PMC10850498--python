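"""Synthetic 4D phantom generator with known ground-truth rigid motion.

Emulates the study conditions of gated middle-ear microtomography: a series
of ``n_phases`` (default 10) reconstructed 3D volumes at 2.75 um voxels, in
which 2-4 independently moving textured rigid bodies (ossicle stand-ins)
oscillate over a static background shell (temporal-bone stand-in), with
peak rotations of 0-2 degrees about a prescribed axis and peak translations
of 0-3 voxels, following a sinusoid over the stimulation cycle.

Every body carries a frozen low-pass-filtered random texture: like the
ossicles' internal vascular channels, the internal gradients make
intensity-based registration well-conditioned (a uniform body would leave
rotation unobservable).

Motion convention
-----------------
A body's pose at cycle fraction ``s`` is a rotation by
``angle_amplitude * sin(2*pi*(s + phase_offset))`` about ``motion_axis``
through the body center, followed by a translation
``translation_amplitude * sin(2*pi*(s + phase_offset))`` (component-wise).
Phase ``j`` is evaluated at ``s = j / n_phases`` (window start, the
ascending-zero-crossing reference), so the recorded ground truth
``T_j`` — the motion from phase 0 to phase j — is the identity at ``j = 0``
and exactly periodic over the cycle.  A window-center convention
(``s = (j + 0.5) / n_phases``) is available via ``phase_time``; ground
truth is then still expressed relative to phase 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AxisAngle, RigidTransform, from_axis_angle
from .postgating import FrameClock, GatingSignal
from .series import PhaseSeries

__all__ = [
    "BodySpec",
    "PhantomSpec",
    "GroundTruth",
    "generate_phase_volumes",
    "generate_timing",
    "add_noise",
    "default_three_body_spec",
]

SHAPES = ("capsule", "L-prism", "arch", "ellipsoid")

#: margin (voxels) a body must keep from the grid boundary at every phase,
#: covering the cubic-spline support of the resampler.
_EDGE_MARGIN = 2.0


@dataclass(frozen=True)
class BodySpec:
    """One moving rigid body: shape, texture and sinusoidal motion law."""

    label: str
    shape: str
    center: tuple[float, float, float]  # (x, y, z) voxels
    size: tuple[float, float, float]  # half-extents, voxels
    texture_seed: int = 0
    motion_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    angle_amplitude_deg: float = 0.0
    translation_amplitude: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_offset: float = 0.0
    intensity: float = 1.0
    texture_contrast: float = 0.35

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; choose from {SHAPES}")
        axis = np.asarray(self.motion_axis, dtype=float)
        if not np.isclose(np.linalg.norm(axis), 1.0, atol=1e-9):
            raise ValueError(f"body {self.label!r}: motion_axis must be a unit vector")
        if not all(s > 0 for s in self.size):
            raise ValueError(f"body {self.label!r}: half-extents must be positive")
        if not 0.0 <= self.phase_offset < 1.0:
            raise ValueError(f"body {self.label!r}: phase_offset must lie in [0, 1)")
        if self.angle_amplitude_deg < 0:
            raise ValueError(f"body {self.label!r}: angle amplitude must be >= 0")

    @property
    def center_a(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def size_a(self) -> np.ndarray:
        return np.asarray(self.size, dtype=float)


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description: grid, bodies, background shell, noise."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)  # (x, y, z) voxels
    voxel_size_um: float = 2.75
    n_phases: int = 10
    bodies: tuple[BodySpec, ...] = ()
    background_intensity: float = 0.15
    shell_thickness: float = 3.0  # static background shell, voxels; 0 disables
    noise_sigma: float = 0.0
    seed: int = 0
    phase_time: str = "start"  # "start" | "center" window-time convention

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("need n_phases >= 2")
        if any(g < 32 for g in self.grid_shape):
            raise ValueError("grid_shape components must be >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.phase_time not in ("start", "center"):
            raise ValueError("phase_time must be 'start' or 'center'")
        object.__setattr__(self, "bodies", tuple(self.bodies))

    def phase_fractions(self) -> np.ndarray:
        j = np.arange(self.n_phases, dtype=float)
        off = 0.5 if self.phase_time == "center" else 0.0
        return (j + off) / self.n_phases


@dataclass
class GroundTruth:
    """Per body, per phase: the rigid motion from phase 0, at the body center.

    ``transforms[label][j]`` is ``M(s_j) o M(s_0)^{-1}`` so phase 0 is always
    the identity; ``raw[label]`` records the generating per-phase axis, angle
    and translation of the absolute (rest-relative) pose.
    """

    transforms: dict[str, list[RigidTransform]]
    raw: dict[str, dict[str, np.ndarray]]
    phase_fractions: np.ndarray

    def body_labels(self) -> list[str]:
        return list(self.transforms)


def _pose_at(body: BodySpec, s: float) -> RigidTransform:
    """Absolute (rest-relative) pose of a body at cycle fraction s."""
    amp = np.sin(2.0 * np.pi * (s + body.phase_offset))
    angle = body.angle_amplitude_deg * amp
    R = from_axis_angle(AxisAngle(np.asarray(body.motion_axis, float), abs(angle)))
    if angle < 0:
        R = R.T
    t = np.asarray(body.translation_amplitude, float) * amp
    return RigidTransform(R, t, body.center_a)


def _body_mask(
    body: BodySpec, grid_xyz: tuple[int, int, int], lo_xyz=(0, 0, 0)
) -> np.ndarray:
    """Boolean occupancy of the body at rest, on a [z, y, x] (sub)grid whose
    voxel (0,0,0) sits at absolute position ``lo_xyz``."""
    nx, ny, nz = grid_xyz
    ox, oy, oz = lo_xyz
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float) + oz,
        np.arange(ny, dtype=float) + oy,
        np.arange(nx, dtype=float) + ox,
        indexing="ij",
    )
    cx, cy, cz = body.center_a
    sx, sy, sz = body.size_a
    u, v, w = xx - cx, yy - cy, zz - cz
    if body.shape == "ellipsoid":
        return (u / sx) ** 2 + (v / sy) ** 2 + (w / sz) ** 2 <= 1.0
    if body.shape == "capsule":
        # cylinder along z with hemispherical caps
        r = min(sx, sy)
        half = max(sz - r, 0.0)
        wz = np.clip(w, -half, half)
        return u**2 + v**2 + (w - wz) ** 2 <= r**2
    if body.shape == "L-prism":
        # vertical bar plus foot: an L in the x-z plane, extruded along y
        bar = (np.abs(u) <= sx * 0.45) & (np.abs(v) <= sy) & (np.abs(w) <= sz)
        foot = (
            (u >= -sx * 0.45)
            & (u <= sx)
            & (np.abs(v) <= sy)
            & (w >= -sz)
            & (w <= -sz * 0.4)
        )
        return bar | foot
    if body.shape == "arch":
        # half-annulus in the x-z plane, extruded along y
        rho = np.sqrt(u**2 + w**2)
        return (rho <= sx) & (rho >= sx * 0.45) & (np.abs(v) <= sy) & (w >= 0)
    raise AssertionError(body.shape)


def _body_template(
    body: BodySpec, grid_xyz: tuple[int, int, int], lo_xyz=(0, 0, 0)
) -> np.ndarray:
    """Textured intensity field of the body at rest (zero outside)."""
    mask = _body_mask(body, grid_xyz, lo_xyz)
    rng = np.random.default_rng(body.texture_seed)
    nz, ny, nx = mask.shape
    tex = ndimage.gaussian_filter(rng.standard_normal((nz, ny, nx)), sigma=1.8)
    inside = tex[mask]
    if inside.size and inside.std() > 0:
        tex = (tex - inside.mean()) / inside.std()
    soft = ndimage.gaussian_filter(mask.astype(float), sigma=0.7)
    return soft * (body.intensity + body.texture_contrast * tex)


def _body_subgrid(body: BodySpec, spec: "PhantomSpec") -> tuple[np.ndarray, np.ndarray]:
    """Integer (lo, hi) absolute (x, y, z) bounds of a box that contains the
    body at every phase, with room for the spline support."""
    reach = np.linalg.norm(body.size_a)  # worst-case rotated half-diagonal
    margin = reach + np.abs(np.asarray(body.translation_amplitude)) + 6.0
    lo = np.floor(body.center_a - margin).astype(int)
    hi = np.ceil(body.center_a + margin).astype(int)
    dims = np.asarray(spec.grid_shape, dtype=int)
    return np.maximum(lo, 0), np.minimum(hi, dims - 1)


def _background(spec: PhantomSpec) -> np.ndarray:
    """Static spherical shell plus faint texture — the temporal-bone stand-in."""
    nx, ny, nz = spec.grid_shape
    vol = np.zeros((nz, ny, nx))
    if spec.shell_thickness <= 0 or spec.background_intensity == 0:
        return vol
    zz, yy, xx = np.meshgrid(
        np.arange(nz, dtype=float),
        np.arange(ny, dtype=float),
        np.arange(nx, dtype=float),
        indexing="ij",
    )
    c = np.array([(nx - 1) / 2, (ny - 1) / 2, (nz - 1) / 2])
    r = np.sqrt((xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
    r_out = min(nx, ny, nz) / 2.0 - _EDGE_MARGIN
    shell = (r <= r_out) & (r >= r_out - spec.shell_thickness)
    rng = np.random.default_rng(spec.seed + 90001)
    tex = ndimage.gaussian_filter(rng.standard_normal(vol.shape), sigma=1.8)
    soft = ndimage.gaussian_filter(shell.astype(float), sigma=0.7)
    return soft * spec.background_intensity * (1.0 + 0.3 * tex)


_J = np.eye(3)[::-1]  # (x,y,z) <-> (z,y,x) basis reversal


def _resample_through_inverse(template: np.ndarray, pose: RigidTransform) -> np.ndarray:
    """Render a rest template at a pose: out(x') = template(pose^{-1} x').

    ``pose`` acts on (x, y, z) coordinates about its origin; the resampler
    works in array index order (z, y, x), so the rotation is conjugated by
    the axis-reversal permutation.
    """
    R_idx = _J @ pose.R @ _J
    c_idx = pose.origin[::-1]
    t_idx = pose.t[::-1]
    A = R_idx.T  # inverse map: x = R^T (x' - c - t) + c
    offset = c_idx - A @ (c_idx + t_idx)
    return ndimage.affine_transform(template, A, offset=offset, order=3, mode="constant")


def _check_inside(body: BodySpec, pose: RigidTransform, grid_xyz, phase: int) -> None:
    """Reject a body whose (rotated bounding box) leaves the grid at a phase."""
    corners = np.array(
        [
            body.center_a + body.size_a * np.array(sgn)
            for sgn in [(i, j, k) for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)]
        ]
    )
    moved = pose.apply(corners)
    hi = np.asarray(grid_xyz, float) - 1.0 - _EDGE_MARGIN
    if np.any(moved < _EDGE_MARGIN) or np.any(moved > hi):
        raise ValueError(
            f"body {body.label!r} exits the grid at phase {phase} "
            f"(bounding corner {moved.min(axis=0)} .. {moved.max(axis=0)})"
        )


def generate_phase_volumes(spec: PhantomSpec) -> tuple[PhaseSeries, GroundTruth]:
    """Render the phantom at every phase and record the exact ground truth.

    Each body is drawn once as a textured rest template, then resampled
    through the inverse of its per-phase pose (cubic spline, so sub-voxel
    motion is representable) and added onto the static background.  The
    background voxels are bitwise identical across phases before noise.
    """
    fractions = spec.phase_fractions()
    bg = _background(spec)
    grid_xyz = tuple(int(g) for g in spec.grid_shape)

    labels = [b.label for b in spec.bodies]
    if len(set(labels)) != len(labels):
        raise ValueError("body labels must be unique")

    transforms: dict[str, list[RigidTransform]] = {b.label: [] for b in spec.bodies}
    raw: dict[str, dict[str, np.ndarray]] = {}
    poses: dict[str, list[RigidTransform]] = {}
    for body in spec.bodies:
        p0 = _pose_at(body, fractions[0])
        per_phase, axes, angles, trs = [], [], [], []
        for j, s in enumerate(fractions):
            pj = _pose_at(body, float(s))
            _check_inside(body, pj, grid_xyz, j)
            per_phase.append(pj)
            amp = np.sin(2.0 * np.pi * (s + body.phase_offset))
            axes.append(np.asarray(body.motion_axis, float))
            angles.append(body.angle_amplitude_deg * amp)
            trs.append(np.asarray(body.translation_amplitude, float) * amp)
            rel = pj.compose(p0.inverse())
            transforms[body.label].append(
                RigidTransform(rel.R, rel.t, body.center_a, phase=j)
            )
        poses[body.label] = per_phase
        raw[body.label] = {
            "axis": np.array(axes),
            "angle_deg": np.array(angles),
            "translation": np.array(trs),
        }

    # each body is rendered on its own subgrid (bounding box over all
    # phases + spline support), so its footprint in the volume is local
    subgrids = {b.label: _body_subgrid(b, spec) for b in spec.bodies}
    templates = {}
    for b in spec.bodies:
        lo, hi = subgrids[b.label]
        shape_xyz = tuple(int(v) for v in (hi - lo + 1))
        templates[b.label] = _body_template(b, shape_xyz, tuple(lo))
    volumes = []
    for j in range(spec.n_phases):
        vol = bg.copy()
        for body in spec.bodies:
            lo, hi = subgrids[body.label]
            pose = poses[body.label][j]
            tmpl = templates[body.label]
            if pose.is_identity(atol=1e-15):
                patch = tmpl
            else:
                local = RigidTransform(pose.R, pose.t, pose.origin - lo)
                patch = _resample_through_inverse(tmpl, local)
            vol[lo[2] : hi[2] + 1, lo[1] : hi[1] + 1, lo[0] : hi[0] + 1] += patch
        volumes.append(vol)

    if spec.noise_sigma > 0:
        volumes = [
            add_noise(v, spec.noise_sigma, seed=spec.seed + 1000 + j)
            for j, v in enumerate(volumes)
        ]

    series = PhaseSeries(volumes, spec.voxel_size_um)
    return series, GroundTruth(transforms, raw, fractions)


def generate_timing(
    n_frames: int,
    exposure_period_ms: float = 0.5,
    exposure_time_ms: float = 0.495,
    f_stim_hz: float = 128.0,
    t0_ms: float = 0.0,
    jitter_sd_ms: float = 0.0,
    seed: int = 0,
) -> tuple[FrameClock, GatingSignal]:
    """Simulate the camera exposure clock and the gating-sine description.

    Timestamps are ``t0 + i * exposure_period`` with optional Gaussian
    jitter; the gating signal is ``sin(2*pi*f*(t - t0))`` so its ascending
    zero crossing reference is ``t0``.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if not 0 < exposure_time_ms <= exposure_period_ms:
        raise ValueError("need 0 < exposure_time <= exposure_period")
    if f_stim_hz <= 0:
        raise ValueError("stimulation frequency must be positive")
    t = t0_ms + np.arange(n_frames, dtype=float) * exposure_period_ms
    if jitter_sd_ms > 0:
        rng = np.random.default_rng(seed)
        t = t + rng.normal(0.0, jitter_sd_ms, size=n_frames)
        t = np.sort(t)
    clock = FrameClock(t, exposure_period_ms, exposure_time_ms)
    return clock, GatingSignal(f_stim_hz, t_ref_ms=t0_ms)


def add_noise(volume: np.ndarray, noise_sigma: float, seed: int = 0) -> np.ndarray:
    """Additive Gaussian noise, reproducible under a fixed seed."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return volume
    rng = np.random.default_rng(seed)
    return volume + rng.normal(0.0, noise_sigma, size=volume.shape)


def default_three_body_spec(
    grid: int = 96,
    noise_sigma: float = 0.0,
    seed: int = 0,
    angle_scale: float = 1.0,
    translation_scale: float = 1.0,
) -> PhantomSpec:
    """The stock three-ossicle phantom: malleus/incus as rotating levers with
    near-colinear axes, stapes as a mostly translating piston.

    Amplitudes sit in the study's regime (rotations under 2 degrees, peak
    translations under 3 voxels); ``angle_scale``/``translation_scale``
    rescale all bodies together, e.g. to emulate a change in stimulation
    sound pressure level.
    """
    g = grid
    q = g / 96.0  # positions scale with the grid
    ax_m = np.array([0.20, 0.95, 0.10])
    ax_m /= np.linalg.norm(ax_m)
    ax_i = np.array([0.25, 0.93, 0.05])
    ax_i /= np.linalg.norm(ax_i)
    ax_s = np.array([0.0, 0.0, 1.0])
    bodies = (
        BodySpec(
            label="malleus",
            shape="capsule",
            center=(30 * q, 48 * q, 46 * q),
            size=(9 * q, 9 * q, 20 * q),
            texture_seed=seed + 11,
            motion_axis=tuple(ax_m),
            angle_amplitude_deg=1.2 * angle_scale,
            translation_amplitude=(0.8 * translation_scale, 0.0, 0.3 * translation_scale),
        ),
        BodySpec(
            label="incus",
            shape="L-prism",
            center=(62 * q, 48 * q, 50 * q),
            size=(11 * q, 8 * q, 16 * q),
            texture_seed=seed + 23,
            motion_axis=tuple(ax_i),
            angle_amplitude_deg=0.9 * angle_scale,
            translation_amplitude=(0.5 * translation_scale, 0.2 * translation_scale, 0.0),
        ),
        BodySpec(
            label="stapes",
            shape="ellipsoid",
            center=(48 * q, 24 * q, 60 * q),
            size=(10 * q, 7 * q, 7 * q),
            texture_seed=seed + 37,
            motion_axis=tuple(ax_s),
            angle_amplitude_deg=0.15 * angle_scale,
            translation_amplitude=(1.2 * translation_scale, 0.4 * translation_scale, 0.0),
        ),
    )
    return PhantomSpec(
        grid_shape=(g, g, g),
        n_phases=10,
        bodies=bodies,
        noise_sigma=noise_sigma,
        seed=seed,
    )
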