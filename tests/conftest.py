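import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_alignment(rng, n=10, length=100, n_variable=8):
    """A random clean alignment with some polymorphic columns."""
    bases = np.array(list("ACGT"))
    background = rng.choice(bases, size=length)
    rows = np.tile(background, (n, 1))
    cols = rng.choice(length, size=min(n_variable, length), replace=False)
    for c in cols:
        alt = rng.choice([b for b in "ACGT" if b != background[c]])
        carriers = rng.choice(n, size=rng.integers(1, n), replace=False)
        for i in carriers:
            rows[i, c] = alt
    return ["".join(r) for r in rows]
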