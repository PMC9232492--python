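"""Shared fixtures: small, fast simulation configurations and synthetic traces."""

import numpy as np
import pytest

from polfrap import (
    AcquisitionConfig,
    GeometryConfig,
    KineticModel,
    RawTrace,
    SimulationConfig,
)


@pytest.fixture
def baseline_model():
    return KineticModel(f_free=0.25, f_prom=0.45, f_elong=0.30, t_prom=30.0, t_elong=23 * 60.0)


@pytest.fixture
def fast_sim():
    """Small, short simulation for smoke-level Monte Carlo checks."""
    return SimulationConfig(
        n_particles=2000,
        dt=0.1,
        seed=7,
        acquisition=AcquisitionConfig(recovery_duration=60.0),
    )


@pytest.fixture
def simple_trace():
    """Hand-sized raw trace: 30 pre-bleach frames then a bleached plateau."""
    n = 60
    bleach = 30
    times = 0.4 * np.arange(n)
    strip = np.full(n, 510.0)
    strip[bleach:] = 110.0
    return RawTrace(
        cell_id="cell_a",
        times=times,
        strip_intensity=strip,
        background_intensity=np.full(n, 10.0),
        bleach_frame_index=bleach,
        condition_label="0 J",
    )
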