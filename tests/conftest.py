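import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20150156)


@pytest.fixture
def random_pi(rng):
    """Strictly positive random codon frequencies (61 states)."""
    pi = rng.dirichlet(np.full(61, 5.0))
    pi = np.maximum(pi, 1e-4)
    return pi / pi.sum()
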