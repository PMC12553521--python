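"""File formats: telemetry/feature CSV, NIfTI volumes, JSON reports."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .activity import TelemetrySeries
from .synthetic import VoxelVolume

__all__ = [
    "write_telemetry_csv",
    "read_telemetry_csv",
    "write_volume_nifti",
    "read_volume_nifti",
    "write_json",
    "to_jsonable",
]


def write_telemetry_csv(
    days: list[TelemetrySeries], path: str | Path, sparse: bool = True
) -> Path:
    """Write telemetry as CSV.

    With ``sparse=True`` only rows at which the cumulative distance
    changes (plus the first and last sample of each day) are stored.
    Bout detection and rest/duration extraction depend only on the
    movement samples, so the sparse form is loss-free for the activity
    metrics while shrinking files by ~30x.
    """
    path = Path(path)
    frames = []
    for d in days:
        df = d.to_frame()
        if sparse and len(df) > 2:
            inc = np.diff(d.cum_distance, prepend=d.cum_distance[0]) > 0
            inc[0] = inc[-1] = True
            df = df.loc[inc]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_telemetry_csv(path: str | Path) -> list[TelemetrySeries]:
    df = pd.read_csv(path)
    out = []
    for (sid, day), g in df.groupby(["subject_id", "day"], sort=True):
        out.append(
            TelemetrySeries(
                subject_id=str(sid),
                day_index=int(day),
                t=g["t_seconds"].to_numpy(),
                cum_distance=g["cum_distance_m"].to_numpy(),
            )
        )
    return out


def write_volume_nifti(volume: VoxelVolume, path: str | Path) -> Path:
    """Store intensities with the voxel size in the affine; the defect
    mask rides along as a second file with suffix ``_mask``."""
    path = Path(path)
    affine = np.diag([volume.voxel_size] * 3 + [1.0])
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float32),
                             affine), path)
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    nib.save(
        nib.Nifti1Image(volume.defect_mask.astype(np.uint8), affine),
        mask_path,
    )
    return path


def read_volume_nifti(path: str | Path) -> VoxelVolume:
    path = Path(path)
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    mask_path = path.with_name(path.name.replace(".nii", "_mask.nii"))
    if mask_path.exists():
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(img.shape, dtype=bool)
    return VoxelVolume(
        intensities=np.asarray(img.dataobj, dtype=float),
        voxel_size=voxel,
        defect_mask=mask,
    )


def to_jsonable(obj):
    """Best-effort conversion of analysis objects to JSON-safe values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            k: to_jsonable(v)
            for k, v in dataclasses.asdict(obj).items()
            if not isinstance(v, np.ndarray)
        }
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_json(data, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(to_jsonable(data), indent=2, sort_keys=True))
    return path
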