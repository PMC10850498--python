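"""Retrospective phase gating of a projection stream.

A periodic motion (the sound-driven vibration of the middle ear) is sampled
by acquiring projection frames continuously over many stimulation cycles.
Each frame is assigned to one of ``n_phases`` equal time windows of the
stimulation period, using the camera exposure timestamps and the gating
sine's ascending-zero-crossing reference time.  Phase 0 starts AT the
ascending zero crossing; window ``j`` covers ``[j, j+1) * period/n_phases``
after it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GatingSignal",
    "FrameClock",
    "PhaseGrid",
    "PhaseAssignment",
    "detect_zero_crossing",
    "assign_phases",
    "bin_statistics",
    "flatdark_correct",
]


@dataclass(frozen=True)
class GatingSignal:
    """Stimulation sine description: frequency and the time of an ascending
    zero crossing (the reference of phase 0)."""

    f_stim_hz: float
    t_ref_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.f_stim_hz <= 0:
            raise ValueError("stimulation frequency must be positive")

    @property
    def period_ms(self) -> float:
        return 1000.0 / self.f_stim_hz


@dataclass(frozen=True)
class FrameClock:
    """Camera exposure timestamps (ms), one per frame, strictly increasing."""

    timestamps_ms: np.ndarray
    exposure_period_ms: float
    exposure_time_ms: float

    def __post_init__(self) -> None:
        ts = np.asarray(self.timestamps_ms, dtype=float).reshape(-1)
        if ts.size == 0:
            raise ValueError("need at least one timestamp")
        if ts.size > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not 0 < self.exposure_time_ms <= self.exposure_period_ms:
            raise ValueError("need 0 < exposure_time <= exposure_period")
        object.__setattr__(self, "timestamps_ms", ts)

    @property
    def n_frames(self) -> int:
        return int(self.timestamps_ms.size)

    def exposure_within_tenth_period(self, gating: GatingSignal) -> bool:
        """Blur guard: exposure must not exceed one tenth of the stimulation
        period, else intra-frame motion smears the projections."""
        return self.exposure_time_ms <= gating.period_ms / 10.0 + 1e-12


@dataclass(frozen=True)
class PhaseGrid:
    """The subdivision of one stimulation period into equal phase windows."""

    n_phases: int
    period_ms: float

    def __post_init__(self) -> None:
        if self.n_phases < 2:
            raise ValueError("need at least 2 phases")
        if self.period_ms <= 0:
            raise ValueError("period must be positive")

    @property
    def bin_width_ms(self) -> float:
        return self.period_ms / self.n_phases

    @property
    def bin_start_times_ms(self) -> np.ndarray:
        return np.arange(self.n_phases) * self.bin_width_ms

    @property
    def bin_center_times_ms(self) -> np.ndarray:
        return (np.arange(self.n_phases) + 0.5) * self.bin_width_ms


@dataclass(frozen=True)
class PhaseAssignment:
    """Partition of the frame stream into phase windows."""

    phase_of_frame: np.ndarray  # (n_frames,) int
    n_phases: int
    angles_deg: np.ndarray | None = None  # optional per-frame rotation angles

    def __post_init__(self) -> None:
        ph = np.asarray(self.phase_of_frame, dtype=int).reshape(-1)
        if ph.size and (ph.min() < 0 or ph.max() >= self.n_phases):
            raise ValueError("phase index out of range")
        object.__setattr__(self, "phase_of_frame", ph)
        if self.angles_deg is not None:
            ang = np.asarray(self.angles_deg, dtype=float).reshape(-1)
            if ang.size != ph.size:
                raise ValueError("angle schedule length must match frame count")
            object.__setattr__(self, "angles_deg", ang)

    @property
    def n_frames(self) -> int:
        return int(self.phase_of_frame.size)

    def frames_in_phase(self, j: int) -> np.ndarray:
        return np.flatnonzero(self.phase_of_frame == j)

    def counts(self) -> np.ndarray:
        return np.bincount(self.phase_of_frame, minlength=self.n_phases)


def detect_zero_crossing(times_ms: np.ndarray, trace: np.ndarray) -> float:
    """Time of the first ascending zero crossing of a sampled gating trace.

    Linearly interpolates between the bracketing samples.  A sample exactly
    at zero followed by a positive sample counts as the crossing itself.
    """
    t = np.asarray(times_ms, dtype=float).reshape(-1)
    s = np.asarray(trace, dtype=float).reshape(-1)
    if t.size != s.size or t.size < 2:
        raise ValueError("trace and times must have equal length >= 2")
    for i in range(s.size - 1):
        if s[i] == 0.0 and s[i + 1] > 0.0:
            return float(t[i])
        if s[i] < 0.0 <= s[i + 1]:
            # linear interpolation of the sign change
            return float(t[i] + (t[i + 1] - t[i]) * (-s[i]) / (s[i + 1] - s[i]))
    raise ValueError("no ascending zero crossing found in gating trace")


def assign_phases(clock: FrameClock, gating: GatingSignal, n_phases: int = 10) -> PhaseAssignment:
    """Sort frames into phase windows of the stimulation cycle.

    phase(i) = floor( frac((t_i - t_ref) * f) * n_phases ), using the
    exposure-START timestamp; mathematical frac maps times before the
    reference into [0, 1) so early frames are still binned.
    """
    if n_phases < 2:
        raise ValueError("need at least 2 phases")
    period = gating.period_ms
    # modulo-then-floordiv keeps frames that sit exactly on a window boundary
    # in the correct window (the direct frac(dt*f) route loses that to the
    # inexact binary representation of f/1000)
    tau = (clock.timestamps_ms - gating.t_ref_ms) % period
    phase = (tau // (period / n_phases)).astype(int)
    np.clip(phase, 0, n_phases - 1, out=phase)  # guard float roundoff at tau -> period
    return PhaseAssignment(phase, n_phases)


def bin_statistics(assignment: PhaseAssignment) -> dict:
    """Per-phase occupancy (and angular coverage if a schedule is attached).

    Returns a dict with counts, mean/min/max count, and — when per-frame
    rotation angles are present — each phase's angular span and largest
    angular gap (wrap-around included), the quantities that decide whether a
    post-gated subset still supports tomographic reconstruction.
    """
    counts = assignment.counts()
    stats: dict = {
        "counts": counts.tolist(),
        "n_frames": int(counts.sum()),
        "mean_count": float(counts.mean()),
        "min_count": int(counts.min()),
        "max_count": int(counts.max()),
    }
    if assignment.angles_deg is not None:
        cov = []
        for j in range(assignment.n_phases):
            idx = assignment.frames_in_phase(j)
            if idx.size == 0:
                cov.append({"phase": j, "span_deg": 0.0, "max_gap_deg": 360.0})
                continue
            a = np.sort(assignment.angles_deg[idx] % 360.0)
            if a.size == 1:
                cov.append({"phase": j, "span_deg": 0.0, "max_gap_deg": 360.0})
                continue
            gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
            cov.append(
                {
                    "phase": j,
                    "span_deg": float(a[-1] - a[0]),
                    "max_gap_deg": float(gaps.max()),
                }
            )
        stats["angular_coverage"] = cov
    return stats


def flatdark_correct(
    projection: np.ndarray, dark: np.ndarray, flat: np.ndarray
) -> tuple[np.ndarray, int]:
    """Standard flat/dark-field normalization (proj - dark) / (flat - dark).

    Pixels where the denominator vanishes are set to 0; their count is
    returned so runs can audit detector defects.  An all-zero denominator is
    rejected outright.
    """
    projection = np.asarray(projection, dtype=float)
    dark = np.asarray(dark, dtype=float)
    flat = np.asarray(flat, dtype=float)
    if not (projection.shape == dark.shape == flat.shape):
        raise ValueError("projection, dark and flat must share a shape")
    denom = flat - dark
    bad = denom == 0
    if bad.all():
        raise ValueError("flat - dark is zero everywhere; cannot correct")
    out = np.zeros_like(projection)
    np.divide(projection - dark, denom, out=out, where=~bad)
    return out, int(bad.sum())
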