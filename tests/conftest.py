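import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class ForcedRNG:
    """Stand-in RNG that replays scripted uniforms and permutations.

    ``uniforms`` feeds successive ``random()`` calls; ``orders`` feeds
    successive ``permutation(n)`` calls (identity when exhausted).
    """

    def __init__(self, uniforms=(), orders=()):
        self._uniforms = list(uniforms)
        self._orders = list(orders)

    def random(self):
        if not self._uniforms:
            raise AssertionError("ForcedRNG ran out of scripted uniforms")
        return self._uniforms.pop(0)

    def permutation(self, n):
        if self._orders:
            order = self._orders.pop(0)
            assert len(order) == n
            return np.asarray(order)
        return np.arange(n)


@pytest.fixture
def forced_rng():
    return ForcedRNG


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
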