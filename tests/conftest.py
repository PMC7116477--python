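"""Shared fixtures: reference models and simulated records (session-scoped)."""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from dirspec import (  # noqa: E402
    DirectedGraph,
    MVARModel,
    TimeSeriesData,
    build_periodic_model,
    simulate,
    spectral_matrix,
)

FS = 200.0


@pytest.fixture(scope="session")
def common_drive_graph():
    """Three nodes, edges X->Y at lag 2 and X->Z at lag 3 (lagged common drive)."""
    return DirectedGraph(3, ((0, 1, 2), (0, 2, 3)))


@pytest.fixture(scope="session")
def common_drive_model(common_drive_graph):
    return build_periodic_model(common_drive_graph)


@pytest.fixture(scope="session")
def common_drive_data(common_drive_model):
    return simulate(common_drive_model, 50_000, seed=2024, fs=FS)


@pytest.fixture(scope="session")
def common_drive_spectral(common_drive_data):
    return spectral_matrix(common_drive_data, seg_len=256)


@pytest.fixture(scope="session")
def unidirectional_model():
    """Two nodes, X -> Y at lag 2, gentle resonance (oracle-friendly)."""
    graph = DirectedGraph(2, ((0, 1, 2),))
    return build_periodic_model(graph, pole_radius=0.6, coupling=0.3)


@pytest.fixture(scope="session")
def unidirectional_data(unidirectional_model):
    return simulate(unidirectional_model, 100_000, seed=7, fs=FS)


@pytest.fixture(scope="session")
def unidirectional_spectral(unidirectional_data):
    return spectral_matrix(unidirectional_data, seg_len=256)


@pytest.fixture(scope="session")
def white_noise_data():
    rng = np.random.default_rng(11)
    return TimeSeriesData(rng.standard_normal((2, 40_000)), fs=FS)


@pytest.fixture(scope="session")
def white_noise_spectral(white_noise_data):
    return spectral_matrix(white_noise_data, seg_len=256)


@pytest.fixture(scope="session")
def ar1_model():
    return MVARModel(
        coeffs=np.array([[[0.9]]]), constants=np.zeros(1), noise_cov=np.eye(1)
    )
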