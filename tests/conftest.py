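import numpy as np
import pytest

from depthgauge import synthetic as syn


@pytest.fixture(scope="session")
def reference_connectome():
    """Deterministic connectome fixture (cells, matrix)."""
    spec = syn.ConnectomeFixtureSpec(deterministic=True)
    return syn.make_reference_connectome(spec, seed=0)


@pytest.fixture(scope="session")
def seeded_connectome():
    """Seeded (random synapse counts) connectome fixture."""
    return syn.make_reference_connectome(seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
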