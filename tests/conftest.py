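"""Shared fixtures: small synthetic study areas built once per session."""

import numpy as np
import pytest

from coastnest import pipeline, synth
from coastnest.hexgrid import PlanarHexIndexer


def small_control_points(length_deg: float = 28.0, n: int = 80) -> np.ndarray:
    """A ~3,200-km gently meandering coastline (for fast unit tests)."""
    u = np.linspace(0.0, 1.0, n)
    lon = length_deg * u
    lat = 3.0 + 2.0 * np.sin(2.0 * np.pi * 2.0 * u)
    return np.column_stack([lon, lat])


@pytest.fixture(scope="session")
def small_config():
    return synth.default_config(7, control_points=small_control_points(),
                                n_timesteps=240)


@pytest.fixture(scope="session")
def small_study(small_config):
    return pipeline.run_study(small_config)


@pytest.fixture(scope="session")
def study_seed1():
    """Full-size default study area (~480 cells), shared across tests."""
    return pipeline.run_study(seed=1)


@pytest.fixture()
def indexer():
    return PlanarHexIndexer()
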