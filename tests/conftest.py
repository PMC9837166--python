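import numpy as np
import pytest

import convscan as cs
from convscan.subst_model import (
    ExchangeabilityMatrix,
    StationaryProfile,
    build_rate_model,
)


@pytest.fixture(scope="session")
def rodent_tree():
    return cs.rodent_tree()


@pytest.fixture(scope="session")
def rodent_clades():
    return cs.rodent_focal_clades()


@pytest.fixture(scope="session")
def jtt_S():
    return cs.jtt_exchangeabilities()


@pytest.fixture(scope="session")
def jtt_model(jtt_S):
    return build_rate_model(jtt_S, cs.jtt_frequencies())


@pytest.fixture
def two_state_model():
    """Uniform 2-state chain: normalised Q = [[-1, 1], [1, -1]]."""
    S = ExchangeabilityMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    pi = StationaryProfile(np.array([0.5, 0.5]))
    return build_rate_model(S, pi)


def random_profile(rng, n=20, floor=1e-3):
    pi = rng.dirichlet(np.ones(n))
    pi = np.maximum(pi, floor)
    return StationaryProfile(pi / pi.sum())


def random_model(rng, S=None, n=20):
    if S is None:
        import convscan as _cs

        S = _cs.jtt_exchangeabilities()
    return build_rate_model(S, random_profile(rng, n=n))
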