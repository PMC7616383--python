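"""Shared fixtures: small grids and acquisitions that run in seconds."""

import numpy as np
import pytest

from svifwi import (
    AcquisitionGeometry,
    SolverConfig,
    VelocityModel,
    ricker,
)


@pytest.fixture(scope="session")
def small_config():
    """Solver settings for a 40x40 toy domain."""
    return SolverConfig(sponge_cells=8, check_every=1000)


@pytest.fixture(scope="session")
def homogeneous_model():
    return VelocityModel(np.full((40, 40), 1500.0), 1e-3)


@pytest.fixture(scope="session")
def heterogeneous_model():
    """Mildly heterogeneous 40x40 model (smooth random speed)."""
    rng = np.random.default_rng(7)
    c = 1500.0 + 30 * rng.standard_normal((40, 40)).cumsum(axis=0) / 40
    return VelocityModel(np.clip(c, 1400, 1600), 1e-3)


@pytest.fixture(scope="session")
def small_geometry():
    """Two sources, four receivers inside the 40 mm toy domain."""
    return AcquisitionGeometry(
        sources=[[0.012, 0.010], [0.028, 0.010]],
        receivers=[[0.012, 0.030], [0.020, 0.030], [0.028, 0.030],
                   [0.020, 0.012]])


@pytest.fixture(scope="session")
def small_wavelet():
    """370 kHz Ricker, 45 us record at 0.15 us -> 300 steps."""
    return ricker(370e3, 0.15e-6, 300)
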