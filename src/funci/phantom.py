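"""Synthetic phantom forward model.

The generator inverts the phase-conductivity relation σ ≈ ∇²φ±/(2μ0ω): each
tissue compartment is given a *quadratic* clean phase

    φ(r) = (μ0·ω·σ_true / 3) · ‖r − r0‖²   (r in metres, shared centre r0)

whose analytic Laplacian is exactly 2·μ0·ω·σ_true, so the ground truth lies
inside the parabolic-fit reconstruction's exactness class.  That separates
algorithm-correctness tests from model-error tests; a Gaussian-bump phase
helper is provided to exercise non-exact fits.

A stimulus-locked activation adds a further quadratic term inside an ROI,
scaled by a unit-peak gamma-like response shape, so the framewise ground
truth is σ_true + amplitude·h(t − onset).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .containers import (
    GM,
    MU0,
    WM,
    AcquisitionMeta,
    DynamicPhaseSeries,
    MagnitudeVolume,
    PhaseVolume,
    StimulusSchedule,
    TissueLabelMap,
    VoxelGrid,
    wrap_to_2pi,
)

#: Resting tissue conductivities used by the default phantoms, S/m
#: (white matter 0.42, grey matter 0.64 at 3 T).
SIGMA_WM = 0.42
SIGMA_GM = 0.64

_DEFAULT_MAGNITUDE = {1: 0.9, 2: 1.0, 3: 1.1}  # GM, WM, CSF


@dataclass(frozen=True)
class Primitive:
    """Geometric region: box/slab (half-extents) or sphere/ellipsoid (radii).

    ``center`` and ``size`` are in voxel coordinates.
    """

    kind: str  # 'box' | 'slab' | 'sphere' | 'ellipsoid'
    center: tuple[float, float, float]
    size: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape, dtype=float)
        d = [idx[a] - self.center[a] for a in range(3)]
        if self.kind in ("box", "slab"):
            m = np.ones(shape, dtype=bool)
            for a in range(3):
                m &= np.abs(d[a]) <= self.size[a]
            return m
        if self.kind in ("sphere", "ellipsoid"):
            q = sum((d[a] / self.size[a]) ** 2 for a in range(3))
            return q <= 1.0
        raise ValueError(f"unknown primitive kind {self.kind!r}")


@dataclass(frozen=True)
class Compartment:
    region: Primitive
    label: int  # tissue code 1..3
    sigma: float  # S/m
    magnitude: float | None = None
    phase_offset: float = 0.0


@dataclass(frozen=True)
class ResponseShape:
    """Unit-peak gamma-like curve h(t) = (t/tp)^a · exp(a·(1 − t/tp)), t ≥ 0.

    Defaults emulate a conductivity response that rises at stimulus onset,
    peaks shortly after a 0.5 s stimulus ends and returns to baseline within
    a few seconds of the peak.
    """

    peak_time: float = 0.7  # s
    shape: float = 2.0  # dimensionless gamma exponent

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.clip(t / self.peak_time, 0.0, None)
        with np.errstate(invalid="ignore"):
            h = np.where(t > 0, x**self.shape * np.exp(self.shape * (1.0 - x)), 0.0)
        return h


@dataclass(frozen=True)
class Activation:
    roi: Primitive
    amplitude: float  # S/m at the response peak
    response: ResponseShape = field(default_factory=ResponseShape)
    schedule: StimulusSchedule = None  # type: ignore[assignment]


@dataclass(frozen=True)
class PhantomSpec:
    grid: VoxelGrid
    compartments: tuple[Compartment, ...]
    noise_std: float = 0.0  # rad
    wrap: bool = False
    activation: Activation | None = None
    seed: int = 0
    n_frames: int = 220
    meta: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    phase_center: tuple[float, float, float] | None = None  # voxel coords
    magnitude_ripple: float = 0.02

    def __post_init__(self):
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")
        for c in self.compartments:
            if c.sigma < 0:
                raise ValueError("sigma_true must be >= 0")


@dataclass
class PhantomTruth:
    sigma_map: np.ndarray  # S/m, NaN outside compartments
    activation_mask: np.ndarray  # bool
    response_times: np.ndarray | None  # s, 0.1 s grid
    response_values: np.ndarray | None  # S/m (amplitude · h)
    phase_clean: PhaseVolume


def _paint(spec: PhantomSpec):
    shape = spec.grid.shape
    labels = np.zeros(shape, dtype=np.int16)
    sigma = np.full(shape, np.nan)
    mag = np.zeros(shape)
    masks = []
    for comp in spec.compartments:
        m = comp.region.mask(shape)
        if np.any(labels[m] != 0):
            raise ValueError("compartments overlap")
        labels[m] = comp.label
        sigma[m] = comp.sigma
        mag[m] = comp.magnitude if comp.magnitude is not None else _DEFAULT_MAGNITUDE[comp.label]
        masks.append(m)
    return labels, sigma, mag, masks


def _r2_metres(spec: PhantomSpec) -> np.ndarray:
    """Squared distance to the shared phase centre, m²."""
    shape = spec.grid.shape
    c = spec.phase_center
    if c is None:
        c = tuple((s - 1) / 2.0 for s in shape)
    h = spec.grid.spacing_m
    idx = np.indices(shape, dtype=float)
    return sum(((idx[a] - c[a]) * h[a]) ** 2 for a in range(3))


def _clean_phase(spec: PhantomSpec, masks, r2) -> np.ndarray:
    omega = spec.meta.omega
    phase = np.zeros(spec.grid.shape)
    for comp, m in zip(spec.compartments, masks):
        phase[m] = (MU0 * omega * comp.sigma / 3.0) * r2[m] + comp.phase_offset
    return phase


def _magnitude(spec: PhantomSpec, mag: np.ndarray) -> MagnitudeVolume:
    if spec.magnitude_ripple:
        nx, ny, nz = spec.grid.shape
        x, y, z = np.indices(spec.grid.shape, dtype=float)
        ripple = (
            np.sin(2 * np.pi * x / nx) * np.sin(2 * np.pi * y / ny) * np.sin(2 * np.pi * z / nz)
        )
        mag = mag * (1.0 + spec.magnitude_ripple * ripple)
    return MagnitudeVolume(mag, spec.grid)


def make_static_phantom(spec: PhantomSpec):
    """Return (PhaseVolume, MagnitudeVolume, TissueLabelMap, PhantomTruth)."""
    labels, sigma, mag, masks = _paint(spec)
    r2 = _r2_metres(spec)
    clean = _clean_phase(spec, masks, r2)
    rng = np.random.default_rng(spec.seed)
    noisy = clean + rng.normal(0.0, spec.noise_std, clean.shape) if spec.noise_std else clean.copy()
    if spec.wrap:
        phase = PhaseVolume(wrap_to_2pi(noisy), spec.grid, wrapped=True)
    else:
        phase = PhaseVolume(noisy, spec.grid, wrapped=False)
    act_mask = (
        spec.activation.roi.mask(spec.grid.shape)
        if spec.activation is not None
        else np.zeros(spec.grid.shape, dtype=bool)
    )
    truth = PhantomTruth(
        sigma_map=sigma,
        activation_mask=act_mask,
        response_times=None,
        response_values=None,
        phase_clean=PhaseVolume(clean, spec.grid, wrapped=False),
    )
    return phase, _magnitude(spec, mag), TissueLabelMap(labels, spec.grid), truth


def make_dynamic_phantom(spec: PhantomSpec):
    """Return (DynamicPhaseSeries, MagnitudeVolume, TissueLabelMap, PhantomTruth, StimulusSchedule).

    Per frame, σ(t) = σ_true + amplitude·Σ_events h(t − actual onset) inside
    the activation ROI; the phase is rebuilt per frame from σ(t) and frame
    values are taken at the frame's mid-acquisition time.  Noise is drawn
    independently per frame from one seeded stream.
    """
    if spec.activation is None or spec.activation.schedule is None:
        raise ValueError("dynamic phantom requires an activation with a schedule")
    act = spec.activation
    sched = act.schedule
    labels, sigma, mag, masks = _paint(spec)
    r2 = _r2_metres(spec)
    clean0 = _clean_phase(spec, masks, r2)
    roi = act.roi.mask(spec.grid.shape) & (labels > 0)

    meta = spec.meta
    mid_times = (np.arange(spec.n_frames) + 0.5) * meta.dynamic_duration
    onsets = sched.actual_onsets
    if onsets.size and onsets.max() > spec.n_frames * meta.dynamic_duration:
        raise ValueError("schedule extends beyond the series duration")

    # activation phase term carries the same quadratic profile, so the
    # framewise analytic Laplacian matches 2·μ0·ω·(σ + A·h)
    act_quad = np.zeros(spec.grid.shape)
    act_quad[roi] = (MU0 * meta.omega * act.amplitude / 3.0) * r2[roi]

    rng = np.random.default_rng(spec.seed)
    frames = []
    for t in mid_times:
        h_t = float(act.response(t - onsets).sum()) if onsets.size else 0.0
        vals = clean0 + act_quad * h_t
        if spec.noise_std:
            vals = vals + rng.normal(0.0, spec.noise_std, vals.shape)
        if spec.wrap:
            frames.append(PhaseVolume(wrap_to_2pi(vals), spec.grid, wrapped=True))
        else:
            frames.append(PhaseVolume(vals, spec.grid, wrapped=False))
    series = DynamicPhaseSeries(frames, meta.dynamic_duration, meta)

    rt = np.arange(0.0, 12.0 + 1e-9, 0.1)
    truth = PhantomTruth(
        sigma_map=sigma,
        activation_mask=roi,
        response_times=rt,
        response_values=act.amplitude * act.response(rt),
        phase_clean=PhaseVolume(clean0, spec.grid, wrapped=False),
    )
    return series, _magnitude(spec, mag), TissueLabelMap(labels, spec.grid), truth, sched


# ---------------------------------------------------------------------------
# default study phantoms


def default_static_spec(
    shape=(64, 64, 64),
    spacing=(3.0, 3.0, 3.0),
    noise_std: float = 0.0,
    wrap: bool = False,
    seed: int = 0,
) -> PhantomSpec:
    """Two-slab brain-like phantom: WM 0.42 S/m and GM 0.64 S/m.

    The slabs split the foreground along x with a 2-voxel background margin;
    the shared phase centre sits on the interface so the clean phase is
    continuous there to within a small in-plane quadratic term.
    """
    nx, ny, nz = shape
    half_y = (ny - 5) / 2.0
    half_z = (nz - 5) / 2.0
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    mid = nx // 2  # WM: 2..mid-1, GM: mid..nx-3
    wm = Compartment(
        Primitive("box", ((2 + mid - 1) / 2.0, cy, cz), ((mid - 3) / 2.0, half_y, half_z)),
        label=WM,
        sigma=SIGMA_WM,
    )
    gm = Compartment(
        Primitive("box", ((mid + nx - 3) / 2.0, cy, cz), ((nx - 3 - mid) / 2.0, half_y, half_z)),
        label=GM,
        sigma=SIGMA_GM,
    )
    grid = VoxelGrid(shape, spacing)
    return PhantomSpec(
        grid=grid,
        compartments=(wm, gm),
        noise_std=noise_std,
        wrap=wrap,
        seed=seed,
        phase_center=(mid - 0.5, cy, cz),
    )


def default_schedule(
    n_cycles: int = 16,
    first_onset: float = 3.6,
    period: float = 16.8,
    duration: float = 0.5,
    contrast: float = 0.45,
    seed: int = 0,
) -> StimulusSchedule:
    """The jittered response-function estimation design: 0.5 s events whose
    onsets are jittered from −0.3 s to 1.2 s in 0.1 s increments in
    semi-randomised (seeded) order."""
    jitters = np.round(np.arange(-0.3, 1.2 + 1e-9, 0.1), 10)
    rng = np.random.default_rng(seed)
    order = rng.permutation(jitters.size)
    jit = np.resize(jitters[order], n_cycles)
    onsets = first_onset + period * np.arange(n_cycles)
    return StimulusSchedule(onsets, duration, jit, contrast)


def default_dynamic_spec(
    amplitude: float = 0.1,
    noise_std: float = 0.05,
    seed: int = 0,
    shape=(32, 32, 24),
    spacing=(3.75, 3.75, 3.75),
    n_frames: int = 220,
    n_cycles: int = 16,
) -> PhantomSpec:
    """Dynamic funCI phantom emulating the response-function estimation scans:
    3.75 mm voxels, 1.2 s dynamic scans, 220 dynamics, 16 jittered 0.5 s
    stimulus cycles, and a stimulus-locked conductivity increase throughout
    the grey-matter compartment."""
    nx, ny, nz = shape
    cy, cz = (ny - 1) / 2.0, (nz - 1) / 2.0
    half_y = (ny - 5) / 2.0
    half_z = (nz - 5) / 2.0
    x_split = max(4, nx // 4)  # WM: 2..x_split, GM: x_split+1..nx-3
    wm = Compartment(
        Primitive("box", ((2 + x_split) / 2.0, cy, cz), ((x_split - 2) / 2.0, half_y, half_z)),
        label=WM,
        sigma=SIGMA_WM,
    )
    gm_c = ((x_split + 1 + nx - 3) / 2.0, cy, cz)
    gm_h = ((nx - 4 - x_split) / 2.0, half_y, half_z)
    gm = Compartment(Primitive("box", gm_c, gm_h), label=GM, sigma=SIGMA_GM)
    sched = default_schedule(n_cycles=n_cycles, seed=seed)
    meta = AcquisitionMeta(dynamic_duration=1.2)
    act = Activation(roi=Primitive("box", gm_c, gm_h), amplitude=amplitude, schedule=sched)
    return PhantomSpec(
        grid=VoxelGrid(shape, spacing),
        compartments=(wm, gm),
        noise_std=noise_std,
        wrap=False,
        activation=act,
        seed=seed,
        n_frames=n_frames,
        meta=meta,
    )


def gaussian_bump_phase(
    grid: VoxelGrid, amplitude: float = 1.0, width_mm: float = 30.0
) -> PhaseVolume:
    """Smooth band-limited test phase (Gaussian bump) for non-exact-fit tests."""
    shape = grid.shape
    h = grid.spacing_m
    c = tuple((s - 1) / 2.0 for s in shape)
    idx = np.indices(shape, dtype=float)
    r2 = sum(((idx[a] - c[a]) * h[a]) ** 2 for a in range(3))
    w = width_mm * 1e-3
    return PhaseVolume(amplitude * np.exp(-r2 / (2 * w * w)), grid, wrapped=False)


def interior_mask(labels: TissueLabelMap, code: int, margin: int) -> np.ndarray:
    """Voxels of a tissue compartment at least ``margin`` voxels from any
    boundary (other tissue, background or volume edge)."""
    m = labels.labels == code
    if margin <= 0:
        return m
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(m, structure=structure, iterations=margin, border_value=0)
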