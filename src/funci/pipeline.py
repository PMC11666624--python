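"""High-level funCI pipeline: denoise → reconstruct → pool → fit → GLM.

Ties the stage modules together behind one configuration record, used both
by the command-line interface and by scripted analyses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .containers import (
    AcquisitionMeta,
    DynamicPhaseSeries,
    MagnitudeVolume,
    StimulusSchedule,
    TissueLabelMap,
)
from .denoise import DiffusionParams, denoise_tissues
from .glm import DEFAULT_T_THRESHOLD, build_design, fit_glm, threshold_map
from .recon import ConductivityMap, KernelSpec, recon_series
from .response import (
    PooledTimecourse,
    ResponseFunction,
    fit_response,
    pool_jittered,
    select_response_voxels,
)

#: Diffusion setting for the synthetic-phantom analyses.  The 400-iteration
#: default targets whole-brain in-vivo volumes; for compartments a few tens
#: of voxels across, the diffusion time iterations·dt must stay small
#: compared with the compartment's Neumann relaxation time (L/π)², or the
#: quadratic phase curvature (hence σ) is itself smoothed away.  The
#: zero-flux boundary layer (~√(2·iters·dt) voxels) additionally compounds
#: with the ±4-voxel kernel reach, so phantom ROIs should also be eroded by
#: PHANTOM_ROI_EROSION from any tissue boundary (see docs/methods.md).
PHANTOM_DIFFUSION = DiffusionParams(iterations=8, dt=0.18)

#: Voxels to erode phantom analysis ROIs away from tissue boundaries.
PHANTOM_ROI_EROSION = 6


def phantom_analysis_roi(labels: TissueLabelMap, code: int = 1,
                         margin: int = PHANTOM_ROI_EROSION) -> np.ndarray:
    """Interior core of a phantom tissue compartment, eroded ``margin``
    voxels from any boundary (falling back to shallower erosion for small
    phantoms so the ROI is never empty)."""
    from .phantom import interior_mask

    for m in range(margin, -1, -1):
        roi = interior_mask(labels, code, m)
        if roi.any():
            return roi
    raise ValueError(f"no voxels with tissue code {code}")


@dataclass(frozen=True)
class ResponseOptions:
    order: int = 10
    alpha: float | None = None  # None = automatic golden-section selection
    resolution: float = 0.1  # s, pooled grid
    pre_window: float = 1.8  # s, per-cycle pre-onset window


@dataclass(frozen=True)
class GlmOptions:
    t_threshold: float = DEFAULT_T_THRESHOLD
    drift: bool = False
    fdr_q: float | None = None


@dataclass(frozen=True)
class RunConfig:
    kernel: KernelSpec = field(default_factory=KernelSpec)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    response: ResponseOptions = field(default_factory=ResponseOptions)
    glm: GlmOptions = field(default_factory=GlmOptions)
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        """Build from a nested mapping, rejecting unknown keys with their path."""
        doc = dict(doc or {})
        kwargs = {}
        blocks = {
            "kernel": KernelSpec,
            "diffusion": DiffusionParams,
            "response": ResponseOptions,
            "glm": GlmOptions,
        }
        for name, klass in blocks.items():
            sub = dict(doc.pop(name, {}) or {})
            known = {f.name for f in dataclasses.fields(klass)}
            unknown = set(sub) - known
            if unknown:
                raise ValueError(f"unknown config key(s): {name}.{sorted(unknown)[0]}")
            if "max_extent" in sub:
                sub["max_extent"] = tuple(sub["max_extent"])
            kwargs[name] = klass(**sub)
        for scalar in ("seed", "log_level"):
            if scalar in doc:
                kwargs[scalar] = doc.pop(scalar)
        if doc:
            raise ValueError(f"unknown config key(s): {sorted(doc)[0]}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def provenance(self) -> dict:
        doc = dataclasses.asdict(self)
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return {
            "funci_version": __version__,
            "config": doc,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": self.seed,
        }


def preprocess_series(
    series: DynamicPhaseSeries,
    labels: TissueLabelMap,
    diffusion: DiffusionParams | None,
) -> DynamicPhaseSeries:
    """Per-tissue diffusion denoising of every frame (None = skip)."""
    if diffusion is None or diffusion.iterations == 0:
        return series
    frames = [denoise_tissues(f, labels, diffusion) for f in series.frames]
    return DynamicPhaseSeries(frames, series.dynamic_duration, series.meta)


def estimate_response(
    series: DynamicPhaseSeries,
    magnitude: MagnitudeVolume,
    labels: TissueLabelMap,
    schedule: StimulusSchedule,
    roi: np.ndarray,
    kernel: KernelSpec = KernelSpec(),
    diffusion: DiffusionParams | None = PHANTOM_DIFFUSION,
    options: ResponseOptions = ResponseOptions(),
    assume_unwrapped: bool = True,
):
    """Full response-function chain: denoise → recon_series →
    select_response_voxels → pool_jittered → fit_response.

    Returns (ResponseFunction, PooledTimecourse, selected voxel set, maps).
    """
    pre = preprocess_series(series, labels, diffusion)
    maps = recon_series(pre, magnitude, labels, kernel, assume_unwrapped=assume_unwrapped)
    voxels = select_response_voxels(
        maps, schedule, roi, series.meta, pre_window=options.pre_window
    )
    tc = pool_jittered(
        maps,
        schedule,
        voxels,
        series.meta,
        resolution=options.resolution,
        pre_window=options.pre_window,
    )
    rf = fit_response(tc, order=options.order, alpha=options.alpha or "auto")
    return rf, tc, voxels, maps


def activation_maps(
    maps: list[ConductivityMap],
    schedule: StimulusSchedule,
    rf: ResponseFunction,
    meta: AcquisitionMeta,
    options: GlmOptions = GlmOptions(),
):
    """GLM stage: build the CRF-convolved design, fit, threshold.

    Returns (ActivationMaps, boolean activation mask).
    """
    frame_times = (np.arange(len(maps)) + 0.5) * meta.dynamic_duration
    design = build_design(schedule, rf, frame_times, drift=options.drift)
    am = fit_glm(maps, design)
    am.threshold = options.t_threshold
    return am, threshold_map(am)
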