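import numpy as np
import pytest

from neurostim import LatencyGrid, NetworkParams, SimConfig


@pytest.fixture
def canonical() -> NetworkParams:
    return NetworkParams.canonical()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def grid() -> LatencyGrid:
    return LatencyGrid()


@pytest.fixture(scope="session")
def spontaneous_recording():
    """A 20-minute canonical recording with ground truth (session-scoped)."""
    from neurostim import generate_spontaneous_recording

    cfg = SimConfig(params=NetworkParams.canonical())
    return generate_spontaneous_recording(cfg, 1200.0, np.random.default_rng(42))
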