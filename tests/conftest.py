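import numpy as np
import pytest
from hypothesis import settings

from biofilmosc import load_parameters

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def p():
    """Default parameter set in internal units."""
    return load_parameters({})


@pytest.fixture(scope="session")
def trace_150um_20h(p):
    """The default 1D run: 150 µm initial width, 20 hours (shared across
    tests because it is the reference condition for several comparisons)."""
    from biofilmosc import run_1d
    return run_1d(0.150, p, 20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
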