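import numpy as np
import pytest

from avopinion import ModelParams


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(12345)))


@pytest.fixture
def tiny_params():
    """A small, fast instance used for engine-level contract tests."""
    return ModelParams(
        n_patients=20,
        n_doctors=5,
        n_initiators=2,
        max_ticks=60,
    )
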