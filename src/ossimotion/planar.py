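"""Planar quality-control views of a phase series.

Two quick 2D reads on whether and where the sample moves, usable before any
registration: (1) the intensity profile along a fixed line, extracted at
every phase and stacked into a position-by-phase matrix — a moving edge
(e.g. the tympanic membrane) traces a sinusoid across the columns, and the
shift between the two extreme columns estimates the peak-to-peak
displacement; (2) the per-pixel standard deviation across phases of a
reslice, which cancels static structure and highlights moving edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import PhaseSeries

__all__ = [
    "ProfileMatrix",
    "StdProjectionImage",
    "profile_over_phases",
    "extreme_shift",
    "std_projection",
]


@dataclass
class ProfileMatrix:
    """Intensity along one line, per phase: shape (n_samples, n_phases)."""

    matrix: np.ndarray
    start: np.ndarray  # (x, y, z) voxels
    stop: np.ndarray
    spacing: float  # voxels between successive samples
    voxel_size_um: float

    @property
    def n_phases(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class StdProjectionImage:
    """Per-pixel dispersion of a reslice across phases (>= 0 everywhere;
    exactly 0 where the content is identical across phases)."""

    image: np.ndarray
    voxel_size_um: float


def profile_over_phases(
    series: PhaseSeries, start, stop, spacing: float = 1.0
) -> ProfileMatrix:
    """Sample the intensity profile along a line for every phase.

    ``start``/``stop`` are (x, y, z) voxel coordinates; samples are placed
    every ``spacing`` voxels along the segment (endpoints included) and
    interpolated linearly.
    """
    start = np.asarray(start, dtype=float).reshape(3)
    stop = np.asarray(stop, dtype=float).reshape(3)
    dims = np.asarray(series.grid_shape_xyz, dtype=float)
    for p, name in ((start, "start"), (stop, "stop")):
        if np.any(p < 0) or np.any(p > dims - 1):
            raise ValueError(f"line {name} point {p} lies outside the grid")
    length = float(np.linalg.norm(stop - start))
    n_samples = max(int(np.floor(length / spacing)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + ts[:, None] * (stop - start)[None, :]
    coords = pts[:, ::-1].T  # map_coordinates wants (z, y, x) rows
    cols = [
        ndimage.map_coordinates(series[j], coords, order=1, mode="nearest")
        for j in range(series.n_phases)
    ]
    return ProfileMatrix(
        matrix=np.stack(cols, axis=1),
        start=start,
        stop=stop,
        spacing=float(np.linalg.norm(pts[1] - pts[0])) if n_samples > 1 else spacing,
        voxel_size_um=series.voxel_size_um,
    )


def _pair_shift(a: np.ndarray, b: np.ndarray) -> float:
    """Sub-sample shift of profile b relative to a by cross-correlation with
    parabolic refinement of the peak.

    Correlates the profile gradients: a step edge turns into a localized
    peak, giving a sharp correlation maximum where the raw profiles would
    produce a flat plateau.
    """
    a = np.gradient(a - a.mean())
    b = np.gradient(b - b.mean())
    corr = np.correlate(b, a, mode="full")
    lags = np.arange(-(a.size - 1), a.size)
    k = int(np.argmax(corr))
    lag = float(lags[k])
    if 0 < k < corr.size - 1:
        c0, c1, c2 = corr[k - 1], corr[k], corr[k + 1]
        denom = c0 - 2 * c1 + c2
        if denom != 0:
            lag += 0.5 * (c0 - c2) / denom
    return lag


def extreme_shift(profile: ProfileMatrix) -> tuple[float, tuple[int, int]]:
    """Displacement between the two maximally shifted phases of a profile.

    Cross-correlates every phase pair, picks the pair with the largest
    absolute sub-sample lag (parabolic interpolation around the correlation
    peak), and converts lag x sample-spacing to micrometres.  Returns
    (shift_um, (phase_a, phase_b)) with the later phase shifted by +shift
    relative to the earlier.
    """
    m = profile.matrix
    if m.shape[1] < 2:
        raise ValueError("need at least 2 phases")
    if np.allclose(m.std(axis=0), 0.0):
        raise ValueError("flat profiles carry no features to correlate")
    best = (0.0, (0, 1))
    for i in range(m.shape[1]):
        for j in range(i + 1, m.shape[1]):
            lag = _pair_shift(m[:, i], m[:, j])
            if abs(lag) > abs(best[0]):
                best = (lag, (i, j))
    lag, pair = best
    return lag * profile.spacing * profile.voxel_size_um, pair


def std_projection(reslices: np.ndarray | list[np.ndarray], voxel_size_um: float = 2.75) -> StdProjectionImage:
    """Per-pixel sample standard deviation (n-1 denominator) across phases.

    ``reslices`` is an (n_phases, H, W) stack of the same plane extracted
    from each phase volume; static pixels map to exactly zero, moving edges
    to bright ridges.
    """
    stack = np.asarray(reslices, dtype=float)
    if stack.ndim != 3:
        raise ValueError("expected an (n_phases, H, W) stack")
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 phases for a dispersion image")
    return StdProjectionImage(stack.std(axis=0, ddof=1), voxel_size_um)
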