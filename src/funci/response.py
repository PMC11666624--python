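"""Stimulus-locked conductivity response estimation.

Each dynamic frame's conductivity value is assigned to the halfway point of
its acquisition and expressed relative to the actual (jittered) stimulus
onset of its cycle; because the onsets are jittered in 0.1 s increments,
pooling frames across cycles tiles a 100 ms time grid, an order of magnitude
finer than the frame duration.  The pooled conductivity time course (the
conductivity response function, CRF) is fitted by least squares with an
orthonormal discrete-Laguerre basis (10 functions by default), from which
peak amplitude, peak time and return-to-baseline time are read.

Also provides the repeatability (one-way single-score ICC) and the
peak-vs-stimulus simple linear regression used for duration/contrast series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import AcquisitionMeta, StimulusSchedule
from .recon import ConductivityMap


@dataclass
class PooledTimecourse:
    """Jitter-pooled mean conductivity on a 100 ms grid.

    ``counts`` records the number of (cycle, frame) samples per bin; bins
    with count 0 carry NaN values.
    """

    times: np.ndarray  # s relative to stimulus onset
    values: np.ndarray  # mean conductivity, S/m
    counts: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class ResponseFunction:
    """Fitted conductivity response function with peak metrics.

    ``fitted`` is baseline-subtracted (baseline = weighted mean of pre-onset
    bins) and lives on the nonnegative part of the pooled 100 ms grid;
    ``peak_amplitude`` is its maximum above baseline.
    """

    order: int
    alpha: float
    coefficients: np.ndarray
    times: np.ndarray  # t >= 0 grid
    fitted: np.ndarray
    baseline: float
    peak_amplitude: float
    peak_time: float
    return_to_baseline_time: float | None


@dataclass
class StimulusResponseFit:
    predictor: np.ndarray
    peaks: np.ndarray
    slope: float
    intercept: float
    r_squared: float


# ---------------------------------------------------------------------------
# frame/cycle bookkeeping


def assign_frames(
    schedule: StimulusSchedule,
    frame_times: np.ndarray,
    pre_window: float = 1.8,
) -> list[np.ndarray]:
    """Partition frame indices into stimulus cycles.

    Cycle *i* owns frames whose mid-time falls in
    [onset_i − pre_window, onset_{i+1} − pre_window); cycle boundaries come
    from the events table, never inferred.  ``pre_window`` reserves
    pre-onset baseline frames for each cycle and should exceed the largest
    jitter.
    """
    if len(schedule) == 0:
        raise ValueError("empty stimulus schedule")
    onsets = schedule.cycle_onsets
    if len(onsets) > 1:
        last_period = onsets[-1] - onsets[-2]
    else:
        last_period = frame_times[-1] - onsets[0] + pre_window + 1.0
    bounds = np.concatenate([onsets - pre_window, [onsets[-1] + last_period - pre_window]])
    # nudge boundaries so frames landing exactly on a cycle edge are assigned
    # deterministically (to the later cycle) regardless of float rounding
    bounds = bounds - 1e-6
    out = []
    for i in range(len(onsets)):
        out.append(np.nonzero((frame_times >= bounds[i]) & (frame_times < bounds[i + 1]))[0])
    return out


def _voxel_mask(voxels, shape) -> np.ndarray:
    if isinstance(voxels, np.ndarray) and voxels.dtype == bool:
        return voxels
    m = np.zeros(shape, dtype=bool)
    for v in voxels:
        m[tuple(v)] = True
    return m


def select_response_voxels(
    maps: list[ConductivityMap],
    schedule: StimulusSchedule,
    roi: np.ndarray,
    meta: AcquisitionMeta,
    pre_window: float = 1.8,
) -> set[tuple[int, int, int]]:
    """ROI voxels whose conductivity is greater in the first ON condition
    than in the OFF (baseline) condition.

    The ON value is the first frame whose mid-time follows cycle 1's actual
    onset; the OFF baseline is the mean of that voxel's pre-onset frames of
    cycle 1.  Only voxels valid in all compared frames are eligible.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    if len(schedule) == 0:
        raise ValueError("empty stimulus schedule")
    frame_times = (np.arange(len(maps)) + 0.5) * meta.dynamic_duration
    cycle_frames = assign_frames(schedule, frame_times, pre_window)[0]
    onset = schedule.actual_onsets[0]
    pre = [f for f in cycle_frames if frame_times[f] < onset]
    post = [f for f in cycle_frames if frame_times[f] >= onset]
    if not pre:
        raise ValueError("no pre-onset baseline frames available for cycle 1")
    if not post:
        raise ValueError("no post-onset frames available for cycle 1")
    first_on = post[0]
    used = pre + [first_on]
    ok = roi.copy()
    for f in used:
        ok &= maps[f].valid
    baseline = np.mean([maps[f].values for f in pre], axis=0)
    rise = maps[first_on].values > baseline
    sel = ok & rise
    return {tuple(int(c) for c in idx) for idx in np.argwhere(sel)}


def pool_jittered(
    maps: list[ConductivityMap],
    schedule: StimulusSchedule,
    voxels,
    meta: AcquisitionMeta,
    resolution: float = 0.1,
    pre_window: float = 1.8,
) -> PooledTimecourse:
    """Pool the ROI-mean conductivity of every (cycle, frame) sample onto a
    ``resolution`` (default 100 ms) grid.

    Each frame maps to t = (frame_start + dynamic_duration/2) − (cycle onset
    + jitter); the value is the mean over the given voxels that are valid in
    that frame; samples are assigned to the nearest bin centre with ties to
    the earlier bin.
    """
    vm = _voxel_mask(voxels, maps[0].values.shape)
    if not vm.any():
        raise ValueError("empty voxel set")
    frame_times = (np.arange(len(maps)) + 0.5) * meta.dynamic_duration
    cycles = assign_frames(schedule, frame_times, pre_window)
    onsets = schedule.actual_onsets

    ts, vs = [], []
    for i, frames in enumerate(cycles):
        for f in frames:
            vals = maps[f].values[vm]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            ts.append(frame_times[f] - onsets[i])
            vs.append(float(vals.mean()))
    if not ts:
        raise ValueError("no frames assigned to any cycle")
    t = np.asarray(ts)
    v = np.asarray(vs)
    # nearest bin centre, ties to the earlier bin
    bins = np.ceil(t / resolution - 0.5 - 1e-9).astype(int)
    b0, b1 = bins.min(), bins.max()
    n = b1 - b0 + 1
    counts = np.bincount(bins - b0, minlength=n)
    sums = np.bincount(bins - b0, weights=v, minlength=n)
    with np.errstate(invalid="ignore"):
        values = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    times = (np.arange(b0, b1 + 1)) * resolution
    return PooledTimecourse(times=times, values=values, counts=counts)


# ---------------------------------------------------------------------------
# discrete Laguerre basis and least-squares fitting


def laguerre_basis(order: int, alpha: float, times: np.ndarray) -> np.ndarray:
    """Orthonormal discrete Laguerre functions on the given uniform grid.

    The functions are generated by the standard all-pass recurrence with
    decay parameter α ∈ (0, 1),

        b_0(n) = √(1−α)·α^(n/2),
        b_j(n) = √α·b_j(n−1) + √α·b_{j−1}(n) − b_{j−1}(n−1),

    then re-orthonormalised over the finite grid (QR with positive
    diagonal), which preserves the span while making the columns orthonormal
    over the discrete index to machine precision.  As α→0 the first function
    tends to a unit impulse at the first grid point.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if order < 1:
        raise ValueError("order must be >= 1")
    n = np.asarray(times).size
    if n < order:
        raise ValueError("grid shorter than the basis order")
    B = np.zeros((n, order))
    ra = np.sqrt(alpha)
    B[:, 0] = np.sqrt(1.0 - alpha) * alpha ** (np.arange(n) / 2.0)
    for j in range(1, order):
        prev = B[:, j - 1]
        col = np.zeros(n)
        col[0] = ra * prev[0]
        for i in range(1, n):
            col[i] = ra * col[i - 1] + ra * prev[i] - prev[i - 1]
        B[:, j] = col
    Q, R = np.linalg.qr(B)
    sign = np.sign(np.diag(R))
    sign[sign == 0] = 1.0
    return Q * sign


def _weighted_fit(B, y, w):
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(B * sw[:, None], y * sw, rcond=None)
    resid = y - B @ coef
    return coef, float(np.sum(w * resid**2))


def fit_response(
    tc: PooledTimecourse,
    order: int = 10,
    alpha: float | str | None = "auto",
    baseline_fraction_return: float = 0.05,
) -> ResponseFunction:
    """Least-squares discrete-Laguerre fit of the pooled timecourse.

    The OFF baseline (count-weighted mean of pre-onset bins) is subtracted,
    the causal basis is fitted to the t ≥ 0 bins with count weights, and the
    peak amplitude is the maximum of the fitted curve above baseline.  The
    return-to-baseline time is the first post-peak grid time at which the
    fitted curve falls to ≤ 5% of the peak.  ``alpha='auto'`` selects the
    decay parameter by golden-section search on the weighted residual.
    """
    post = tc.times >= -1e-9
    t_post = tc.times[post]
    v_post = tc.values[post]
    w_post = tc.counts[post].astype(float)
    usable = (w_post > 0) & np.isfinite(v_post)
    if int(usable.sum()) < order:
        raise ValueError(
            f"rank deficiency: {int(usable.sum())} populated bins < order {order}"
        )
    pre = ~post
    w_pre = tc.counts[pre].astype(float)
    if w_pre.sum() > 0:
        baseline = float(np.nansum(tc.values[pre] * w_pre) / w_pre.sum())
    else:
        baseline = 0.0
    y = np.where(usable, v_post - baseline, 0.0)
    w = np.where(usable, w_post, 0.0)

    def solve(a):
        B = laguerre_basis(order, a, t_post)
        coef, rss = _weighted_fit(B, y, w)
        return B, coef, rss

    if alpha in (None, "auto"):
        # golden-section search on (0.05, 0.95)
        gr = (np.sqrt(5.0) - 1.0) / 2.0
        lo, hi = 0.05, 0.95
        c = hi - gr * (hi - lo)
        d = lo + gr * (hi - lo)
        fc = solve(c)[2]
        fd = solve(d)[2]
        for _ in range(40):
            if fc < fd:
                hi, d, fd = d, c, fc
                c = hi - gr * (hi - lo)
                fc = solve(c)[2]
            else:
                lo, c, fc = c, d, fd
                d = lo + gr * (hi - lo)
                fd = solve(d)[2]
        alpha_val = (lo + hi) / 2.0
    else:
        alpha_val = float(alpha)
    B, coef, _ = solve(alpha_val)
    raw = B @ coef

    # In the gaps of a sparsely jittered design the LS expansion is
    # unconstrained and can swing arbitrarily; the stored curve is therefore
    # the fit at populated bins, linearly interpolated across gaps (zero
    # before the first populated bin, matching a causal response).  With
    # full jitter coverage this equals the basis expansion everywhere.
    support = np.nonzero(usable)[0]
    fitted = np.interp(t_post, t_post[support], raw[support], left=0.0,
                       right=raw[support[-1]])
    fitted[support] = raw[support]
    ipk = int(support[np.argmax(fitted[support])])
    peak_amplitude = float(fitted[ipk])
    peak_time = float(t_post[ipk])
    r2b = None
    thresh = baseline_fraction_return * peak_amplitude
    for i in support[support > ipk]:
        if fitted[i] <= thresh:
            r2b = float(t_post[i])
            break
    return ResponseFunction(
        order=order,
        alpha=float(alpha_val),
        coefficients=coef,
        times=t_post,
        fitted=fitted,
        baseline=baseline,
        peak_amplitude=peak_amplitude,
        peak_time=peak_time,
        return_to_baseline_time=r2b,
    )


def stimulus_response_regression(peaks, predictor) -> StimulusResponseFit:
    """Simple linear regression of response peak amplitude on stimulus
    duration or contrast."""
    peaks = np.asarray(peaks, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if peaks.size != predictor.size or peaks.size < 3:
        raise ValueError("need >= 3 matched (predictor, peak) points")
    if np.ptp(predictor) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(predictor, peaks)
    return StimulusResponseFit(
        predictor=predictor,
        peaks=peaks,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def icc_oneway(measurements: np.ndarray) -> float:
    """Single-score one-way intraclass correlation, ICC(1,1).

    ``measurements`` is a subjects × repeats table; the estimate is
    (MSB − MSW) / (MSB + (k−1)·MSW) from the one-way ANOVA decomposition.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 repeats")
    n, k = x.shape
    subj_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msw = np.sum((x - subj_means[:, None]) ** 2) / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0:
        return 0.0
    return float((msb - msw) / denom)
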