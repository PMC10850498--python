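"""Readers and writers for the pipeline's on-disk formats.

Volumes travel as TIFF slice stacks in ``phase_00 ... phase_NN`` directories
(slice index = z); coordinate tables (sub-volumes, ROI points) as CSV in
(x, y, z) voxel order, 0-based; transforms and motion results as JSON with
row-major rotation matrices; timing as CSV; configs as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .displacement import ROIPointSet, SineFit
from .geometry import RigidTransform
from .kinematics import OssicleMotion
from .postgating import FrameClock, GatingSignal, PhaseAssignment
from .registration import SubVolumeSpec
from .series import PhaseSeries

__all__ = [
    "write_phase_series",
    "read_phase_series",
    "write_ground_truth",
    "write_timing_csv",
    "read_timing_csv",
    "read_gating_yaml",
    "write_assignment",
    "read_subvolume_csv",
    "read_roi_csv",
    "transforms_to_json",
    "transforms_from_json",
    "motion_to_dict",
    "write_json",
    "read_yaml",
]


def write_phase_series(series: PhaseSeries, out_dir: str | Path) -> None:
    """One TIFF per z-slice, under phase_00 ... phase_NN directories."""
    out_dir = Path(out_dir)
    for j in range(series.n_phases):
        d = out_dir / f"phase_{j:02d}"
        d.mkdir(parents=True, exist_ok=True)
        vol = series[j].astype(np.float32)
        for z in range(vol.shape[0]):
            tifffile.imwrite(d / f"slice_{z:04d}.tif", vol[z])


def read_phase_series(in_dir: str | Path, voxel_size_um: float = 2.75) -> PhaseSeries:
    in_dir = Path(in_dir)
    phase_dirs = sorted(in_dir.glob("phase_*"))
    if not phase_dirs:
        raise FileNotFoundError(f"no phase_* directories under {in_dir}")
    volumes = []
    for d in phase_dirs:
        slices = sorted(d.glob("*.tif")) + sorted(d.glob("*.tiff"))
        if not slices:
            raise FileNotFoundError(f"no TIFF slices under {d}")
        volumes.append(np.stack([tifffile.imread(s) for s in slices]).astype(float))
    return PhaseSeries(volumes, voxel_size_um)


def _transform_record(T: RigidTransform, **extra) -> dict:
    rec = {
        "R": [float(v) for v in T.R.reshape(-1)],  # row-major
        "t": [float(v) for v in T.t],
        "origin": [float(v) for v in T.origin],
        "phase": int(T.phase),
        "converged": bool(T.converged),
        "units": "voxels",
    }
    rec.update(extra)
    return rec


def _transform_from_record(rec: dict) -> RigidTransform:
    return RigidTransform(
        np.array(rec["R"], dtype=float).reshape(3, 3),
        np.array(rec["t"], dtype=float),
        np.array(rec["origin"], dtype=float),
        phase=int(rec.get("phase", 0)),
        converged=bool(rec.get("converged", True)),
    )


def write_ground_truth(gt, path: str | Path) -> None:
    doc = {
        "phase_fractions": [float(s) for s in gt.phase_fractions],
        "bodies": {
            label: [_transform_record(T) for T in ts]
            for label, ts in gt.transforms.items()
        },
    }
    write_json(doc, path)


def write_timing_csv(clock: FrameClock, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(clock.n_frames),
            "timestamp_ms": clock.timestamps_ms,
        }
    ).to_csv(path, index=False)


def read_timing_csv(
    path: str | Path, exposure_period_ms: float, exposure_time_ms: float
) -> FrameClock:
    df = pd.read_csv(path)
    ts = df.sort_values("frame_index")["timestamp_ms"].to_numpy(dtype=float)
    return FrameClock(ts, exposure_period_ms, exposure_time_ms)


def read_gating_yaml(path: str | Path) -> GatingSignal:
    doc = read_yaml(path)
    return GatingSignal(float(doc["f_stim_hz"]), float(doc.get("t_ref_ms", 0.0)))


def write_assignment(assignment: PhaseAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(assignment.n_frames),
            "phase": assignment.phase_of_frame,
        }
    ).to_csv(path, index=False)


def read_subvolume_csv(path: str | Path) -> list[SubVolumeSpec]:
    """Columns: ossicle_label, cx, cy, cz, hx, hy, hz (voxels, 0-based)."""
    df = pd.read_csv(path)
    return [
        SubVolumeSpec(
            str(r.ossicle_label),
            (float(r.cx), float(r.cy), float(r.cz)),
            (float(r.hx), float(r.hy), float(r.hz)),
        )
        for r in df.itertuples()
    ]


def read_roi_csv(path: str | Path, voxel_size_um: float = 2.75) -> list[ROIPointSet]:
    """Columns: roi_label, ossicle_label, x, y, z; rows sharing a roi_label
    form one point set."""
    df = pd.read_csv(path)
    rois = []
    for (roi_label, ossicle_label), grp in df.groupby(
        ["roi_label", "ossicle_label"], sort=False
    ):
        pts = grp[["x", "y", "z"]].to_numpy(dtype=float)
        rois.append(ROIPointSet(str(roi_label), str(ossicle_label), pts, voxel_size_um))
    return rois


def transforms_to_json(
    per_ossicle: dict[str, list[list[RigidTransform]]], path: str | Path
) -> None:
    doc = {
        label: [[_transform_record(T, sv_index=i) for T in row] for i, row in enumerate(rows)]
        for label, rows in per_ossicle.items()
    }
    write_json(doc, path)


def transforms_from_json(path: str | Path) -> dict[str, list[list[RigidTransform]]]:
    with open(path) as fh:
        doc = json.load(fh)
    return {
        label: [[_transform_from_record(rec) for rec in row] for row in rows]
        for label, rows in doc.items()
    }


def motion_to_dict(motion: OssicleMotion) -> dict:
    return {
        "ossicle_label": motion.ossicle_label,
        "origin": [float(v) for v in motion.origin],
        "phases": [
            {
                "transform": _transform_record(T),
                "axis": [float(v) for v in aa.axis],
                "angle_deg": float(aa.angle_deg),
                "degenerate": bool(aa.degenerate),
                "dispersions": [float(v) for v in motion.dispersions[j]],
                "survivors": [bool(b) for b in motion.survivor_masks[j]],
            }
            for j, (T, aa) in enumerate(
                zip(motion.mean_transforms, motion.mean_axis_angles)
            )
        ],
        "principal_axis": (
            [float(v) for v in motion.principal_axis]
            if motion.principal_axis is not None
            else None
        ),
        "warnings": list(motion.warnings),
    }


def sinefit_to_dict(fit: SineFit) -> dict:
    return {
        "A_um": fit.A_um,
        "two_A_um": fit.peak_to_peak_um,
        "phi_cycles": fit.phi_cycles,
        "f_hz": fit.f_hz,
        "R2": fit.R2,
    }


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
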