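import numpy as np
import pytest

from pretestsim import DistributionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp_spec():
    return DistributionSpec.exponential(1.0)


@pytest.fixture(scope="session")
def unif_spec():
    return DistributionSpec.uniform(0.0, 1.0)


@pytest.fixture(scope="session")
def norm_spec():
    return DistributionSpec.normal(0.0, 1.0)


def mc_tol(p: float, *reps, k: float = 3.0) -> float:
    """k combined Monte-Carlo standard errors for a proportion ``p``
    estimated independently at each replicate count in ``reps``."""
    var = sum(p * (1.0 - p) / r for r in reps)
    return k * var**0.5
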