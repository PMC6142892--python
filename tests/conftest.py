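"""Shared fixtures: small synthetic acquisitions reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from imsdkit.io import AcquisitionMeta
from imsdkit.simulate import SimulationConfig, simulate_stack


def small_config(**overrides) -> SimulationConfig:
    """A quick 64x64, 150-frame acquisition for unit tests."""
    defaults = dict(
        n_particles=8,
        frame_size=64,
        meta=AcquisitionMeta(69.0, 0.065, 150, "sim"),
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def brownian_stack_small():
    cfg = SimulationConfig(
        n_particles=12,
        frame_size=96,
        D=0.05,
        meta=AcquisitionMeta(69.0, 0.065, 200, "sim"),
        seed=11,
    )
    stack, truth = simulate_stack(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def immobile_stack_small():
    cfg = small_config(D=0.0, seed=7)
    stack, truth = simulate_stack(cfg)
    return stack, truth, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
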