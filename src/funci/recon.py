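"""Phase-to-conductivity reconstruction (phase-based MREPT).

Conductivity is estimated voxelwise as σ ≈ ∇²φ± / (2·μ0·ω), where φ± is the
full *transceive* phase: the factor 2 embodies the transceive-phase
assumption that the transmit phase is half the image phase.  The Laplacian is
estimated per axis by *average parabolic fitting*: least-squares parabolas
are fitted separately to {target + left-side row} and {target + right-side
row}, and the axis second derivative is the mean of the available one-sided
curvatures.  Rows are restricted to voxels that share the target's tissue
label and have image amplitude close to the target's, and a one-sided fit is
only accepted when the correlation between fitted and measured phase exceeds
``min_corr``.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .containers import (
    AcquisitionMeta,
    DynamicPhaseSeries,
    MagnitudeVolume,
    PhaseVolume,
    TissueLabelMap,
    VoxelGrid,
)

_ZERO_VAR = 1e-28


@dataclass(frozen=True)
class KernelSpec:
    """All Laplacian-kernel rules in one configurable record.

    ``max_extent`` is the kernel box in voxels (default 9×9×6, the third
    entry conventionally assigned to the slice/partition axis); extents are
    handled as a symmetric reach of ⌊extent/2⌋ voxels per side.  Neighbours
    are included only when they share the target's tissue label and their
    magnitude differs relatively by at most ``amplitude_tol``.  A one-sided
    parabola fit is accepted when its fitted-vs-measured correlation exceeds
    ``min_corr``; a voxel's Laplacian is valid when all three axes are
    accepted and at least ``min_neighbors`` surrounding voxels were used.
    """

    max_extent: tuple[int, int, int] = (9, 9, 6)
    amplitude_tol: float = 0.10
    min_corr: float = 0.7
    min_neighbors: int = 6

    def __post_init__(self):
        if not (0.0 < self.min_corr < 1.0):
            raise ValueError("min_corr must lie in (0, 1)")
        if len(self.max_extent) != 3 or any(int(e) < 1 for e in self.max_extent):
            raise ValueError("max_extent must be three positive integers")
        if self.amplitude_tol < 0:
            raise ValueError("amplitude_tol must be >= 0")
        object.__setattr__(self, "max_extent", tuple(int(e) for e in self.max_extent))

    @property
    def reach(self) -> tuple[int, int, int]:
        return tuple(e // 2 for e in self.max_extent)


@dataclass
class LaplacianMap:
    """∇²φ± in rad/m² with per-voxel validity and kernel diagnostics."""

    values: np.ndarray
    valid: np.ndarray
    neighbor_count: np.ndarray
    grid: VoxelGrid


@dataclass
class ConductivityMap:
    """Voxelwise σ in S/m; NaN where the reconstruction is invalid."""

    values: np.ndarray
    valid: np.ndarray
    grid: VoxelGrid


@lru_cache(maxsize=None)
def _fit_operators(n_side: int):
    """LS operators for a one-sided parabola on positions 0..n_side.

    Returns (w2a, H): ``w2a @ y`` is the fitted second derivative (per
    voxel²) and ``H @ y`` the fitted values.
    """
    x = np.arange(n_side + 1, dtype=float)
    X = np.column_stack([x**2, x, np.ones_like(x)])
    P = np.linalg.pinv(X)
    return 2.0 * P[0], X @ P


def _shift(a: np.ndarray, axis: int, off: int, fill):
    """Array of neighbour values at signed offset ``off`` along ``axis``."""
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if off > 0:
        dst[axis], src[axis] = slice(0, -off), slice(off, None)
    elif off < 0:
        dst[axis], src[axis] = slice(-off, None), slice(0, off)
    out[tuple(dst)] = a[tuple(src)]
    return out


def _corr_fitted(ys: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Pearson correlation between fitted and measured samples.

    With an intercept in the design this equals sqrt(var(ŷ)/var(y)); a
    zero-variance (constant) sample is an exact fit and scores 1.
    """
    yhat = np.einsum("ij,j...->i...", H, ys)
    mean = ys.mean(axis=0)
    var_y = ((ys - mean) ** 2).mean(axis=0)
    var_h = ((yhat - mean) ** 2).mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(var_y > _ZERO_VAR, var_h / np.maximum(var_y, _ZERO_VAR), 1.0)
    return np.sqrt(np.clip(ratio, 0.0, 1.0))


def _side_fits(vals, lab, mag, brain, axis, direction, reach, spec):
    """Vectorised one-sided parabola fits for every voxel along one direction.

    Returns (run, d2, corr): contiguous usable side length (0..reach), the
    one-sided second derivative per voxel² and its fit correlation.
    """
    tol = spec.amplitude_tol
    cum = brain.copy()
    run = np.zeros(vals.shape, dtype=np.int8)
    shifts = []
    for k in range(1, reach + 1):
        off = direction * k
        nb_lab = _shift(lab, axis, off, -1)
        nb_mag = _shift(mag, axis, off, np.inf)
        cum = cum & (nb_lab == lab) & (np.abs(nb_mag - mag) <= tol * mag)
        run += cum
        shifts.append(_shift(vals, axis, off, 0.0))
    d2 = np.zeros(vals.shape)
    corr = np.ones(vals.shape)
    for s in range(2, reach + 1):
        sel = (run == s) & brain
        if not sel.any():
            continue
        ys = np.stack([vals] + shifts[:s], axis=0)
        w2a, H = _fit_operators(s)
        curv = np.tensordot(w2a, ys, axes=1)
        c = _corr_fitted(ys, H)
        d2[sel] = curv[sel]
        corr[sel] = c[sel]
    return run, d2, corr


def laplacian(
    phase: PhaseVolume,
    magnitude: MagnitudeVolume,
    labels: TissueLabelMap,
    spec: KernelSpec = KernelSpec(),
) -> LaplacianMap:
    """Tissue-restricted average-parabolic-fit Laplacian of the phase.

    Per voxel the Laplacian is the sum over the three axes of the accepted
    1D second derivatives, each converted to rad/m² with that axis's
    physical spacing.  A voxel is valid iff all three axes are accepted and
    the number of surrounding voxels used is at least ``min_neighbors``.
    """
    grid = phase.grid
    if not (grid.same_geometry(magnitude.grid) and grid.same_geometry(labels.grid)):
        raise ValueError("phase, magnitude and labels must share one grid")
    vals = np.asarray(phase.values, dtype=float)
    lab = labels.labels
    mag = np.asarray(magnitude.values, dtype=float)
    brain = lab > 0

    lap = np.zeros(grid.shape)
    count = np.zeros(grid.shape, dtype=np.int32)
    all_ok = brain.copy()
    for axis in range(3):
        reach = spec.reach[axis]
        run_p, d2_p, corr_p = _side_fits(vals, lab, mag, brain, axis, +1, reach, spec)
        run_m, d2_m, corr_m = _side_fits(vals, lab, mag, brain, axis, -1, reach, spec)
        used_p = run_p >= 2
        used_m = run_m >= 2
        n_used = used_p.astype(int) + used_m.astype(int)
        with np.errstate(invalid="ignore"):
            value = np.where(
                n_used > 0,
                (d2_p * used_p + d2_m * used_m) / np.maximum(n_used, 1),
                0.0,
            )
        ok = (
            (n_used > 0)
            & (~used_p | (corr_p > spec.min_corr))
            & (~used_m | (corr_m > spec.min_corr))
        )
        h2 = grid.spacing_m[axis] ** 2
        lap += np.where(ok, value / h2, 0.0)
        count += run_p * used_p + run_m * used_m
        all_ok &= ok

    valid = all_ok & (count >= spec.min_neighbors)
    values = np.where(valid, lap, np.nan)
    return LaplacianMap(values=values, valid=valid, neighbor_count=count, grid=grid)


def conductivity(
    lap: LaplacianMap,
    meta: AcquisitionMeta,
    plausibility: tuple[float, float] = (-1.0, 5.0),
) -> ConductivityMap:
    """σ = ∇²φ± / (2·μ0·ω) wherever valid; NaN elsewhere.

    Values outside the ``plausibility`` window (S/m) are flagged invalid.
    """
    if meta.larmor_hz <= 0:
        raise ValueError("larmor_hz must be > 0")
    denom = 2.0 * meta.mu0 * meta.omega
    with np.errstate(invalid="ignore"):
        sigma = lap.values / denom
    valid = lap.valid.copy()
    if plausibility is not None:
        lo, hi = plausibility
        with np.errstate(invalid="ignore"):
            valid &= (sigma >= lo) & (sigma <= hi)
    sigma = np.where(valid, sigma, np.nan)
    return ConductivityMap(values=sigma, valid=valid, grid=lap.grid)


def recon_series(
    series: DynamicPhaseSeries,
    magnitude: MagnitudeVolume,
    labels: TissueLabelMap,
    spec: KernelSpec = KernelSpec(),
    plausibility: tuple[float, float] = (-1.0, 5.0),
    assume_unwrapped: bool = False,
) -> list[ConductivityMap]:
    """Framewise reconstruction of a dynamic series (identical validity logic
    per frame).  Frames must be unwrapped, or ``assume_unwrapped`` set to
    accept externally unwrapped phase stored on the wrapped interval."""
    maps = []
    for frame in series.frames:
        if frame.wrapped and not assume_unwrapped:
            raise ValueError("frames must be unwrapped (or pass assume_unwrapped=True)")
        lap = laplacian(frame, magnitude, labels, spec)
        maps.append(conductivity(lap, series.meta, plausibility))
    return maps


# ---------------------------------------------------------------------------
# reference / diagnostic helpers


def neighborhood(
    target: tuple[int, int, int],
    phase: PhaseVolume,
    magnitude: MagnitudeVolume,
    labels: TissueLabelMap,
    spec: KernelSpec = KernelSpec(),
) -> set[tuple[int, int, int]]:
    """Kernel-candidate voxels around ``target``: within the symmetric box
    reach, sharing the target's tissue label, with close image amplitude."""
    i, j, k = target
    lab = labels.labels
    if lab[i, j, k] == 0:
        raise ValueError("target voxel is background")
    mag = magnitude.values
    m_t = mag[i, j, k]
    rx, ry, rz = spec.reach
    out = set()
    for di in range(-rx, rx + 1):
        for dj in range(-ry, ry + 1):
            for dk in range(-rz, rz + 1):
                if di == dj == dk == 0:
                    continue
                p = (i + di, j + dj, k + dk)
                if any(c < 0 or c >= s for c, s in zip(p, lab.shape)):
                    continue
                if lab[p] != lab[i, j, k]:
                    continue
                if abs(mag[p] - m_t) > spec.amplitude_tol * m_t:
                    continue
                out.add(p)
    return out


def parabolic_second_derivative_1d(
    samples: np.ndarray,
    spacing: float,
    spec: KernelSpec = KernelSpec(),
    target_index: int | None = None,
):
    """Average one-sided parabola fit along a single row of phase samples.

    ``samples`` is an ordered row through the target (NaN marks unusable
    voxels); ``spacing`` is in metres.  Returns ``(second_derivative,
    accepted, fit_corr)`` with the second derivative in rad/m²; a row with
    fewer than 2 usable voxels on both sides is flagged invalid rather than
    raising.
    """
    y = np.asarray(samples, dtype=float)
    t = len(y) // 2 if target_index is None else int(target_index)
    if not np.isfinite(y[t]):
        raise ValueError("target sample must be finite")

    curvs, corrs = [], []
    for direction in (+1, -1):
        side = []
        p = t + direction
        while 0 <= p < y.size and np.isfinite(y[p]) and len(side) < max(spec.reach):
            side.append(y[p])
            p += direction
        if len(side) < 2:
            continue
        ys = np.array([y[t]] + side)
        w2a, H = _fit_operators(len(side))
        curvs.append(float(w2a @ ys))
        corrs.append(float(_corr_fitted(ys[:, None], H)[0]))
    if not curvs:
        return np.nan, False, np.nan
    accepted = all(c > spec.min_corr for c in corrs)
    d2 = float(np.mean(curvs)) / float(spacing) ** 2
    return d2, accepted, min(corrs)


def neighbor_count_histogram(lap: LaplacianMap, labels: TissueLabelMap | None = None):
    """Histogram of surrounding-voxel counts over foreground voxels, plus the
    fraction of voxels with at least six surrounding voxels (the kernel-count
    diagnostic)."""
    mask = labels.labels > 0 if labels is not None else np.isfinite(lap.values) | lap.valid
    counts = lap.neighbor_count[mask]
    hist = np.bincount(counts.ravel())
    frac_ge6 = float((counts >= 6).mean()) if counts.size else float("nan")
    return hist, frac_ge6
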