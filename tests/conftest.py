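import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from canberrank import FeatureUniverse, RankedList

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def universe6() -> FeatureUniverse:
    return FeatureUniverse.auto(6)


@pytest.fixture(scope="session")
def universe100() -> FeatureUniverse:
    return FeatureUniverse.auto(100)


def take(universe: FeatureUniverse, indices) -> RankedList:
    """Ranked list from 0-based universe indices."""
    return RankedList(tuple(universe.features[i] for i in indices))


def random_instance(rng: np.random.Generator, max_pairs: int):
    """Random (L1, L2, universe) whose brute-force enumeration stays
    below ``max_pairs`` completion pairs."""
    import math

    while True:
        p = int(rng.integers(2, 9))
        l1 = int(rng.integers(0, p + 1))
        l2 = int(rng.integers(0, p + 1))
        if math.factorial(p - l1) * math.factorial(p - l2) <= max_pairs:
            break
    universe = FeatureUniverse.auto(p)
    first = take(universe, rng.choice(p, size=l1, replace=False))
    second = take(universe, rng.choice(p, size=l2, replace=False))
    return first, second, universe
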