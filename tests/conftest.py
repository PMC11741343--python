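import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.data_too_large],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_dna(rng, length, n_rate=0.0):
    """Plain helper used across test modules (kept independent of the
    package's own generator so fixture bugs cannot mask generator bugs)."""
    bases = np.array(list("ACGT"))
    seq = bases[rng.integers(0, 4, length)]
    if n_rate > 0:
        mask = rng.random(length) < n_rate
        seq[mask] = "N"
    return "".join(seq)
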