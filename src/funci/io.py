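"""NIfTI, events-TSV and YAML readers/writers.

Volumes travel as NIfTI-1 (.nii/.nii.gz); the events table is a
BIDS-events-like TSV with columns onset/duration/jitter/contrast (seconds,
seconds, seconds, unitless).  Phase is converted to radians at read time:
nibabel applies the header scale/intercept, and an optional ``scale`` factor
covers scanner exports that store phase in other units.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import (
    TWO_PI,
    AcquisitionMeta,
    DynamicPhaseSeries,
    MagnitudeVolume,
    PhaseVolume,
    StimulusSchedule,
    TissueLabelMap,
    VoxelGrid,
    series_from_array,
    wrap_to_2pi,
)

EVENT_COLUMNS = ("onset", "duration", "jitter", "contrast")


def _grid_from_img(img) -> VoxelGrid:
    zooms = img.header.get_zooms()[:3]
    return VoxelGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms), np.asarray(img.affine))


def _load(path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    return nib.load(str(path))


def read_volume(path, expected_kind: str, scale: float | None = None):
    """Read a 3D NIfTI volume as a typed container.

    ``expected_kind`` is one of ``phase``, ``magnitude`` or ``labels``.  Phase
    is detected as wrapped when every finite value lies within [0, 2π) or
    (−π, π]; the latter is rebased onto [0, 2π).
    """
    img = _load(path)
    if len(img.shape) != 3:
        raise ValueError(f"expected a 3D volume, got shape {img.shape}")
    grid = _grid_from_img(img)
    data = np.asarray(img.get_fdata(), dtype=float)
    if expected_kind == "phase":
        if scale is not None:
            data = data * scale
        finite = data[np.isfinite(data)]
        in_0_2pi = finite.size and np.all((finite >= 0) & (finite < TWO_PI))
        in_pm_pi = finite.size and np.all((finite > -np.pi) & (finite <= np.pi))
        if in_0_2pi or in_pm_pi:
            return PhaseVolume(wrap_to_2pi(data), grid, wrapped=True)
        return PhaseVolume(data, grid, wrapped=False)
    if expected_kind == "magnitude":
        return MagnitudeVolume(data, grid)
    if expected_kind == "labels":
        return TissueLabelMap(np.round(data).astype(np.int16), grid)
    raise ValueError(f"unknown kind {expected_kind!r}")


def write_volume(volume, path) -> None:
    """Write any container (or a raw array + grid pair) to NIfTI."""
    if isinstance(volume, TissueLabelMap):
        data, grid = volume.labels.astype(np.int16), volume.grid
    else:
        data, grid = np.asarray(volume.values, dtype=np.float64), volume.grid
    img = nib.Nifti1Image(data, grid.affine)
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def write_array(values: np.ndarray, grid: VoxelGrid, path) -> None:
    values = np.asarray(values, dtype=np.float64)
    img = nib.Nifti1Image(values, grid.affine)
    zooms = grid.spacing + (1.0,) * (values.ndim - 3)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_series(path, meta: AcquisitionMeta, wrapped: bool | None = None) -> DynamicPhaseSeries:
    """Read a 4D NIfTI (or a list of 3D files) as a dynamic phase series.

    Frames are ordered by acquisition index and the first
    ``meta.dummy_scans`` frames are dropped here, at read time, so timing has
    a single place of truth.
    """
    if isinstance(path, (list, tuple)):
        vols = [read_volume(p, "phase") for p in path]
        g0 = vols[0].grid
        for v in vols[1:]:
            if not g0.same_geometry(v.grid):
                raise ValueError("frames have inconsistent voxel grids")
        data = np.stack([v.values for v in vols], axis=-1)
        grid = g0
    else:
        img = _load(path)
        if len(img.shape) != 4:
            raise ValueError(f"expected a 4D volume, got shape {img.shape}")
        grid = _grid_from_img(img)
        data = np.asarray(img.get_fdata(), dtype=float)
    if wrapped is None:
        finite = data[np.isfinite(data)]
        wrapped = bool(finite.size and np.all((finite >= 0) & (finite < TWO_PI)))
    return series_from_array(data, grid, meta, wrapped=wrapped)


def write_series(series: DynamicPhaseSeries, path) -> None:
    data = np.stack([f.values for f in series.frames], axis=-1)
    write_array(data, series.grid, path)


def read_events(path) -> StimulusSchedule:
    """Read a stimulus-event TSV (onset/duration/jitter/contrast)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such events file: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table is missing column(s): {missing}")
    return StimulusSchedule(
        cycle_onsets=df["onset"].to_numpy(float),
        durations=df["duration"].to_numpy(float),
        jitter_offsets=df["jitter"].to_numpy(float),
        contrasts=df["contrast"].to_numpy(float),
    )


def write_events(schedule: StimulusSchedule, path) -> None:
    pd.DataFrame(
        {
            "onset": schedule.cycle_onsets,
            "duration": schedule.durations,
            "jitter": schedule.jitter_offsets,
            "contrast": schedule.contrasts,
        }
    ).to_csv(path, sep="\t", index=False)


def read_acquisition(path) -> AcquisitionMeta:
    """Read AcquisitionMeta from a YAML config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    allowed = {"larmor_hz", "dynamic_duration", "dummy_scans"}
    unknown = set(doc) - allowed
    if unknown:
        raise ValueError(f"unknown acquisition key(s): {sorted(unknown)}")
    return AcquisitionMeta(**doc)
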