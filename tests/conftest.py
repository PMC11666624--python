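import numpy as np
import pytest
from hypothesis import settings

from funci.containers import (
    AcquisitionMeta,
    MagnitudeVolume,
    PhaseVolume,
    TissueLabelMap,
    VoxelGrid,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid16():
    return VoxelGrid((16, 16, 16), (3.0, 3.0, 3.0))


@pytest.fixture(scope="session")
def meta3t():
    return AcquisitionMeta()


def homogeneous_volume(grid, phase_values):
    """Single-tissue volume with uniform magnitude around a phase field."""
    phase = PhaseVolume(phase_values, grid, wrapped=False)
    mag = MagnitudeVolume(np.ones(grid.shape), grid)
    labels = TissueLabelMap(np.ones(grid.shape, dtype=np.int16), grid)
    return phase, mag, labels


@pytest.fixture(scope="session")
def quadratic16(grid16):
    """φ = c·(x²+y²+z²) in voxel units on a homogeneous 16³ volume."""
    c = 0.01
    idx = np.indices(grid16.shape, dtype=float)
    vals = c * sum((idx[a] - 7.5) ** 2 for a in range(3))
    return (*homogeneous_volume(grid16, vals), c)
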