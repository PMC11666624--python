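"""Voxelwise GLM activation mapping on conductivity time series.

The task regressor is the stimulus boxcar convolved with the fitted
conductivity response function on a 100 ms grid, sampled at frame mid-times;
the map of t statistics is thresholded at T > 2.2 by default.  No spatial
smoothing and no multiple-comparison correction are applied by default; an
optional Benjamini–Hochberg FDR flag is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import StimulusSchedule
from .recon import ConductivityMap
from .response import ResponseFunction

DEFAULT_T_THRESHOLD = 2.2


@dataclass
class DesignMatrix:
    """GLM design: task regressor, intercept, optional linear drift.

    All columns except the intercept are mean-centred.
    """

    matrix: np.ndarray  # (T, p)
    names: list[str]
    frame_times: np.ndarray

    @property
    def task_index(self) -> int:
        return self.names.index("task")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.matrix))


@dataclass
class ActivationMaps:
    beta: np.ndarray  # task effect, series units per regressor unit
    tmap: np.ndarray
    dof: int
    threshold: float = DEFAULT_T_THRESHOLD


def build_design(
    schedule: StimulusSchedule,
    rf: ResponseFunction,
    frame_times: np.ndarray,
    drift: bool = False,
    resolution: float = 0.1,
) -> DesignMatrix:
    """Convolve the event boxcar with the response function and sample at
    frame mid-times.

    The boxcar has unit height over each event's (actual, jittered) duration
    on the ``resolution`` grid; the convolution is the plain discrete
    convolution with ``rf.fitted``.
    """
    frame_times = np.asarray(frame_times, dtype=float)
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be increasing")
    t_max = frame_times[-1] + resolution
    n = int(np.ceil(t_max / resolution)) + 1
    grid = np.arange(n) * resolution
    boxcar = np.zeros(n)
    if len(schedule):
        onsets = schedule.actual_onsets
        if onsets.min() < 0 or onsets.max() > t_max:
            raise ValueError("events outside the series time range")
        for onset, dur in zip(onsets, schedule.durations):
            i0 = int(np.ceil(onset / resolution - 1e-9))
            i1 = int(np.ceil((onset + dur) / resolution - 1e-9))
            boxcar[i0 : max(i1, i0 + 1)] = 1.0
    task_dense = np.convolve(boxcar, rf.fitted)[:n]
    idx = np.clip(np.round(frame_times / resolution).astype(int), 0, n - 1)
    task = task_dense[idx]

    cols = [task - task.mean() if len(schedule) else task]
    names = ["task"]
    if drift:
        d = np.linspace(-1.0, 1.0, frame_times.size)
        cols.append(d - d.mean())
        names.append("drift")
    cols.append(np.ones(frame_times.size))
    names.append("intercept")
    X = np.column_stack(cols)
    if len(schedule) and np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(matrix=X, names=names, frame_times=frame_times)


def fit_glm(
    sigma_series: list[ConductivityMap],
    design: DesignMatrix,
    min_valid_fraction: float = 0.9,
) -> ActivationMaps:
    """Ordinary least squares per voxel; t = β/SE(β) for the task column.

    Voxels valid in fewer than ``min_valid_fraction`` of frames are excluded
    (NaN); voxels with a few invalid frames are fitted on their valid frames
    only.
    """
    X = design.matrix
    T, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    if T < p + 2:
        raise ValueError("need at least p + 2 frames")
    shape = sigma_series[0].values.shape
    Y = np.stack([m.values.reshape(-1) for m in sigma_series], axis=0)  # (T, N)
    V = np.stack([m.valid.reshape(-1) for m in sigma_series], axis=0)
    n_valid = V.sum(axis=0)
    eligible = n_valid >= min_valid_fraction * T

    ti = design.task_index
    beta = np.full(Y.shape[1], np.nan)
    tmap = np.full(Y.shape[1], np.nan)
    dof = T - rank

    full = eligible & (n_valid == T)
    if full.any():
        pinv = np.linalg.pinv(X)
        XtXinv_ii = np.linalg.inv(X.T @ X)[ti, ti]
        B = pinv @ Y[:, full]  # (p, n)
        resid = Y[:, full] - X @ B
        rss = np.sum(resid**2, axis=0)
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * XtXinv_ii)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(se > 0, B[ti] / se, 0.0)
        beta[full] = B[ti]
        tmap[full] = tvals

    partial = eligible & (n_valid < T)
    for j in np.nonzero(partial)[0]:
        rows = V[:, j]
        Xj = X[rows]
        if np.linalg.matrix_rank(Xj) < p:
            continue
        yj = Y[rows, j]
        bj, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        rj = yj - Xj @ bj
        dj = rows.sum() - p
        if dj < 1:
            continue
        s2 = float(rj @ rj) / dj
        se = np.sqrt(s2 * np.linalg.inv(Xj.T @ Xj)[ti, ti])
        beta[j] = bj[ti]
        tmap[j] = bj[ti] / se if se > 0 else 0.0

    return ActivationMaps(
        beta=beta.reshape(shape), tmap=tmap.reshape(shape), dof=int(dof)
    )


def threshold_map(maps: ActivationMaps, threshold: float | None = None) -> np.ndarray:
    """Boolean activation mask: t > threshold over valid voxels."""
    th = maps.threshold if threshold is None else threshold
    with np.errstate(invalid="ignore"):
        return np.isfinite(maps.tmap) & (maps.tmap > th)


def fdr_mask(maps: ActivationMaps, q: float = 0.05) -> np.ndarray:
    """Optional Benjamini–Hochberg FDR mask (off by default in the pipeline;
    the standard display threshold is an uncorrected T > 2.2)."""
    finite = np.isfinite(maps.tmap)
    pvals = stats.t.sf(maps.tmap[finite], maps.dof)
    adj = stats.false_discovery_control(pvals, method="bh")
    out = np.zeros_like(maps.tmap, dtype=bool)
    out[finite] = adj <= q
    return out
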