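"""Region-growing 3D phase unwrapping.

The wrapped [0, 2π) interval is divided into six sub-intervals; connected
3D regions (6-connectivity) of voxels falling in one sub-interval are
internally wrap-free, and the merged field is grown from the largest region
by repeatedly absorbing the neighbouring region that shares the largest
border, adding the 2π multiple that minimises the boundary discontinuity
(median of the differences across the shared faces).  This implements the
published region-growing sketch; externally unwrapped phase can bypass the
step entirely.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .containers import TWO_PI, PhaseVolume, wrap_to_2pi

N_INTERVALS = 6


@dataclass
class UnwrapResult:
    phase: PhaseVolume  # wrapped=False
    n_regions_initial: int
    n_merges: int


def _initial_regions(wrapped: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Label connected regions of constant phase sub-interval (6-connectivity)."""
    interval = np.clip((wrapped / (TWO_PI / N_INTERVALS)).astype(int), 0, N_INTERVALS - 1)
    structure = ndimage.generate_binary_structure(3, 1)
    labels = np.zeros(wrapped.shape, dtype=np.int32)
    n_total = 0
    for iv in range(N_INTERVALS):
        m = mask & (interval == iv)
        lab, n = ndimage.label(m, structure=structure)
        labels[m] = lab[m] + n_total
        n_total += n
    return labels, n_total


def _adjacent_pairs(labels: np.ndarray, mask: np.ndarray, wrapped: np.ndarray):
    """Flattened boundary face pairs (region_a, region_b, φ_a, φ_b)."""
    ra, rb, pa, pb = [], [], [], []
    for axis in range(3):
        s0 = [slice(None)] * 3
        s1 = [slice(None)] * 3
        s0[axis] = slice(0, -1)
        s1[axis] = slice(1, None)
        s0, s1 = tuple(s0), tuple(s1)
        la, lb = labels[s0], labels[s1]
        sel = mask[s0] & mask[s1] & (la != lb)
        ra.append(la[sel])
        rb.append(lb[sel])
        pa.append(wrapped[s0][sel])
        pb.append(wrapped[s1][sel])
    return (np.concatenate(ra), np.concatenate(rb), np.concatenate(pa), np.concatenate(pb))


def unwrap(phase: PhaseVolume, mask: np.ndarray, bypass: bool = False) -> UnwrapResult:
    """Unwrap wrapped phase within ``mask``.

    Per connected mask component the result is continuous (no adjacent-voxel
    jump above π for unwrappable fields), differs from the input voxelwise by
    exact 2π multiples, and carries a global per-component 2π offset chosen
    to minimise the mean absolute phase.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    if bypass or not phase.wrapped:
        return UnwrapResult(
            PhaseVolume(phase.values.copy(), phase.grid, wrapped=False), 0, 0
        )
    vals = np.asarray(phase.values, dtype=float)
    if np.all(~np.isfinite(vals[mask])):
        raise ValueError("all-NaN phase inside mask")
    wrapped = wrap_to_2pi(vals)

    labels, n_regions = _initial_regions(wrapped, mask)
    region_sizes = np.bincount(labels[mask].ravel(), minlength=n_regions + 1)

    # group boundary pairs by region edge
    ra, rb, pa, pb = _adjacent_pairs(labels, mask, wrapped)
    edges: dict[int, dict[int, list]] = {}  # region -> neighbour -> [my φ, their φ]
    for a, b, fa, fb in zip(ra, rb, pa, pb):
        edges.setdefault(int(a), {}).setdefault(int(b), []).append((fa, fb))
        edges.setdefault(int(b), {}).setdefault(int(a), []).append((fb, fa))

    k = np.zeros(n_regions + 1)  # 2π multiple per region
    merged = np.zeros(n_regions + 1, dtype=bool)
    n_merges = 0
    remaining = set(range(1, n_regions + 1))

    while remaining:
        # new mask component: seed with its largest region (ties: larger index)
        seed = max(remaining, key=lambda r: (region_sizes[r], r))
        component = [seed]
        merged[seed] = True
        remaining.discard(seed)
        # frontier: neighbour region -> list of (unwrapped merged-side φ, own φ)
        frontier: dict[int, list] = {}

        def absorb(r: int):
            for q, pairs in edges.get(r, {}).items():
                if not merged[q]:
                    kr = k[r]
                    frontier.setdefault(q, []).extend(
                        (fa + TWO_PI * kr, fb) for fa, fb in pairs
                    )

        absorb(seed)
        while frontier:
            # region sharing the largest border; ties to the larger region index
            q = max(frontier, key=lambda r: (len(frontier[r]), r))
            pairs = frontier.pop(q)
            diffs = np.array([fa - fb for fa, fb in pairs])
            k[q] = np.round(np.median(diffs) / TWO_PI)
            merged[q] = True
            remaining.discard(q)
            component.append(q)
            n_merges += 1
            absorb(q)
        # global offset: 2π multiple minimising mean |φ| over the component
        comp_mask = np.isin(labels, component)
        phi = wrapped[comp_mask] + TWO_PI * k[labels[comp_mask]]
        k0 = np.round(np.median(phi) / TWO_PI)
        best = min(
            (k0 - 1, k0, k0 + 1), key=lambda c: np.abs(phi - TWO_PI * c).mean()
        )
        for r in component:
            k[r] -= best

    out = vals.copy()
    out[mask] = wrapped[mask] + TWO_PI * k[labels[mask]]
    return UnwrapResult(
        PhaseVolume(out, phase.grid, wrapped=False), n_regions, n_merges
    )
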