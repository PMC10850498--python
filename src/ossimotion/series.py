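"""The central image container: an ordered series of per-phase 3D volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhaseSeries"]


@dataclass
class PhaseSeries:
    """Ordered set of 3D volumes, one per motion phase, on a shared grid.

    Volumes are numpy arrays indexed ``[z, y, x]`` (TIFF slice-stack order:
    slice index = z).  Coordinate vectors elsewhere in the package are in
    ``(x, y, z)`` order; conversions happen at the array boundary.

    Attributes
    ----------
    volumes : list of (nz, ny, nx) float arrays, all the same shape.
    voxel_size_um : physical voxel edge length, micrometres.
    phase_times_ms : time attributed to each phase within the stimulation
        cycle (used as abscissae for sine fitting).
    """

    volumes: list[np.ndarray]
    voxel_size_um: float = 2.75
    phase_times_ms: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.volumes) < 1:
            raise ValueError("need at least one phase volume")
        shape = self.volumes[0].shape
        for j, v in enumerate(self.volumes):
            if v.ndim != 3:
                raise ValueError(f"phase {j}: volume must be 3D")
            if v.shape != shape:
                raise ValueError(f"phase {j}: shape {v.shape} != {shape}")
        if self.phase_times_ms is not None:
            t = np.asarray(self.phase_times_ms, dtype=float).reshape(-1)
            if t.size != len(self.volumes):
                raise ValueError("phase_times_ms length must match n_phases")
            self.phase_times_ms = t

    @property
    def n_phases(self) -> int:
        return len(self.volumes)

    @property
    def grid_shape_zyx(self) -> tuple[int, int, int]:
        return self.volumes[0].shape

    @property
    def grid_shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.volumes[0].shape
        return (nx, ny, nz)

    def __getitem__(self, j: int) -> np.ndarray:
        return self.volumes[j]

    def __len__(self) -> int:
        return len(self.volumes)
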