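import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230330)


@pytest.fixture(scope="session")
def small_tray():
    """One deterministic 3x5 tray at a small canvas, shared across tests."""
    from candlelite.eggsim import generate_tray

    return generate_tray(3, 5, seed=7, width=160, height=128)
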