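"""Typed in-memory containers for volumetric phase data and stimulus metadata.

All phase values are stored in radians.  Voxel indices are 0-based; physical
voxel spacing enters only when differentiating (second derivatives are
computed per voxel and converted to per-m² with the axis spacing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Magnetic permeability of free space, H/m.
MU0 = 4.0e-7 * np.pi

#: Proton Larmor frequency of the 3 T scanner profile, Hz (ω = 2π·127.76 MHz).
LARMOR_3T_HZ = 127.76e6

#: Tissue label codes.
BACKGROUND, GM, WM, CSF = 0, 1, 2, 3
TISSUE_CODES = frozenset({BACKGROUND, GM, WM, CSF})

TWO_PI = 2.0 * np.pi


def wrap_to_2pi(values: np.ndarray) -> np.ndarray:
    """Rebase phase into [0, 2π).  Idempotent; changes values by exact 2π multiples."""
    out = np.asarray(values, dtype=float) - TWO_PI * np.floor(np.asarray(values) / TWO_PI)
    # floor rounding can land exactly on 2π for values just below a multiple
    out[out >= TWO_PI] -= TWO_PI
    return out


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with physical spacing (mm) and a world affine."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacings must be > 0, got {spacing}")
        affine = self.affine
        if affine is None:
            affine = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "affine", affine)

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        """Voxel spacing in metres."""
        return tuple(s * 1e-3 for s in self.spacing)

    def same_geometry(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


def _check_shape(values: np.ndarray, grid: VoxelGrid, what: str) -> np.ndarray:
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"{what} shape {values.shape} does not match grid {grid.shape}")
    return values


@dataclass
class PhaseVolume:
    """Transceive phase φ± in radians on a voxel grid.

    ``wrapped`` records whether values live on the wrapped [0, 2π) circle or
    are a continuous (unwrapped) field.
    """

    values: np.ndarray
    grid: VoxelGrid
    wrapped: bool = False

    def __post_init__(self):
        self.values = _check_shape(np.asarray(self.values, dtype=float), self.grid, "phase")
        if self.wrapped:
            v = self.values
            finite = np.isfinite(v)
            if np.any((v[finite] < 0) | (v[finite] >= TWO_PI)):
                raise ValueError("wrapped phase must lie in [0, 2π)")

    def rewrapped(self) -> "PhaseVolume":
        return PhaseVolume(wrap_to_2pi(self.values), self.grid, wrapped=True)


@dataclass
class MagnitudeVolume:
    """Image magnitude (arbitrary units, nonnegative)."""

    values: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        self.values = _check_shape(np.asarray(self.values, dtype=float), self.grid, "magnitude")
        finite = np.isfinite(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("magnitude values must be >= 0")


@dataclass
class TissueLabelMap:
    """Integer tissue labels: 0 background, 1 GM, 2 WM, 3 CSF."""

    labels: np.ndarray
    grid: VoxelGrid

    def __post_init__(self):
        labels = _check_shape(np.asarray(self.labels), self.grid, "labels")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integer-valued")
            labels = labels.astype(np.int16)
        codes = set(np.unique(labels).tolist())
        bad = codes - TISSUE_CODES
        if bad:
            raise ValueError(f"unknown tissue code(s): {sorted(bad)}")
        self.labels = labels

    def mask(self, *codes: int) -> np.ndarray:
        """Boolean mask of the given tissue codes (default: any foreground)."""
        if not codes:
            return self.labels > 0
        return np.isin(self.labels, list(codes))


@dataclass
class AcquisitionMeta:
    """Scanner-side constants: Larmor frequency, frame duration, dummy scans."""

    larmor_hz: float = LARMOR_3T_HZ
    dynamic_duration: float = 1.2
    dummy_scans: int = 0
    mu0: float = MU0

    def __post_init__(self):
        if self.larmor_hz <= 0:
            raise ValueError("larmor_hz must be > 0")
        if self.dynamic_duration <= 0:
            raise ValueError("dynamic_duration must be > 0")
        if self.dummy_scans < 0:
            raise ValueError("dummy_scans must be >= 0")

    @property
    def omega(self) -> float:
        """Angular (Larmor) frequency, rad/s.  Derived, never stored."""
        return TWO_PI * self.larmor_hz


@dataclass
class DynamicPhaseSeries:
    """Ordered phase frames sharing one grid; one frame per dynamic scan."""

    frames: list[PhaseVolume]
    dynamic_duration: float
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("series must contain at least one frame")
        if self.dynamic_duration <= 0:
            raise ValueError("dynamic_duration must be > 0")
        g0 = self.frames[0].grid
        for f in self.frames[1:]:
            if not g0.same_geometry(f.grid):
                raise ValueError("all frames must share one voxel grid")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid(self) -> VoxelGrid:
        return self.frames[0].grid

    @property
    def frame_mid_times(self) -> np.ndarray:
        """Mid-acquisition time of each frame, s from series start.

        The conductivity value of a dynamic scan is assigned to the halfway
        point of its acquisition (time to acquire half of k-space).
        """
        return (np.arange(len(self.frames)) + 0.5) * self.dynamic_duration


@dataclass
class StimulusSchedule:
    """Stimulus events: nominal cycle onsets plus per-event jitter offsets.

    The actual stimulus start of event *i* is ``cycle_onsets[i] + jitter_offsets[i]``;
    jittering the onset against the frame clock lets pooled samples tile a time
    grid finer than the frame duration.
    """

    cycle_onsets: np.ndarray
    durations: np.ndarray
    jitter_offsets: np.ndarray
    contrasts: np.ndarray

    def __post_init__(self):
        self.cycle_onsets = np.asarray(self.cycle_onsets, dtype=float)
        n = self.cycle_onsets.size
        self.durations = np.broadcast_to(np.asarray(self.durations, dtype=float), (n,)).copy()
        self.jitter_offsets = np.broadcast_to(
            np.asarray(self.jitter_offsets, dtype=float), (n,)
        ).copy()
        self.contrasts = np.broadcast_to(np.asarray(self.contrasts, dtype=float), (n,)).copy()
        if n and np.any(np.diff(self.cycle_onsets) <= 0):
            raise ValueError("cycle onsets must be strictly increasing")
        if np.any(self.durations <= 0):
            raise ValueError("durations must be > 0")
        if np.any((self.contrasts < 0) | (self.contrasts > 1)):
            raise ValueError("contrast must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.cycle_onsets.size)

    @property
    def actual_onsets(self) -> np.ndarray:
        return self.cycle_onsets + self.jitter_offsets


def series_from_array(
    data: np.ndarray,
    grid: VoxelGrid,
    meta: AcquisitionMeta,
    wrapped: bool = False,
) -> DynamicPhaseSeries:
    """Build a series from a 4D (x, y, z, t) array, dropping dummy frames."""
    data = np.asarray(data, dtype=float)
    if data.ndim != 4:
        raise ValueError("expected a 4D array")
    t0 = meta.dummy_scans
    if t0 >= data.shape[3]:
        raise ValueError("dummy_scans leaves no frames")
    frames = [PhaseVolume(data[..., t], grid, wrapped=wrapped) for t in range(t0, data.shape[3])]
    return DynamicPhaseSeries(frames, meta.dynamic_duration, meta)
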