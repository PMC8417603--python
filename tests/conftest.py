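import numpy as np
import pytest
from hypothesis import settings

from ineqkit import FixtureSpec, UnitDistribution, generate, make_distribution

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

# Worked reference pair: B is A with every component split in two, so the
# two have identical relative (share) structure but different k.
A_UNITS = (360.0, 250.0, 150.0)
B_UNITS = (180.0, 180.0, 125.0, 125.0, 75.0, 75.0)


@pytest.fixture
def dist_a() -> UnitDistribution:
    return make_distribution(A_UNITS)


@pytest.fixture
def dist_b() -> UnitDistribution:
    return make_distribution(B_UNITS)


@pytest.fixture
def uniform5() -> UnitDistribution:
    return make_distribution([20.0] * 5)


@pytest.fixture
def point_mass5() -> UnitDistribution:
    return make_distribution([100.0, 0.0, 0.0, 0.0, 0.0])


def random_distributions(n, seed=0, k_range=(2, 50), family="random_dirichlet",
                         **kwargs):
    """n seeded random distributions with k drawn from k_range."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        k = int(rng.integers(k_range[0], k_range[1] + 1))
        out.append(
            generate(FixtureSpec(family=family, k=k, seed=int(rng.integers(2**31)),
                                 **kwargs))
        )
    return out
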