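import numpy as np
import pytest

from fedbatch_mab import (SolverOptions, load_default_parameters,
                          load_fixture, simulate)
from fedbatch_mab.reactor import FeedArc, FeedPolicy

FIXTURES = ("SPBR", "SP1", "SP2", "SP3")


@pytest.fixture(scope="session")
def params():
    return load_default_parameters()


@pytest.fixture(scope="session")
def scenarios(params):
    return {name: load_fixture(name, params=params) for name in FIXTURES}


@pytest.fixture(scope="session")
def trajectories(scenarios):
    """One default-tolerance simulation per packaged fixture, shared."""
    return {name: simulate(sc) for name, sc in scenarios.items()}


@pytest.fixture(scope="session")
def tight_options():
    return SolverOptions(rtol=1e-8, atol=1e-10)


def random_policy(rng: np.random.Generator, t_f: float = 100.0) -> FeedPolicy:
    """A random but physically sensible equal-arc feed policy."""
    n = int(rng.integers(1, 7))
    arcs = [FeedArc(F_L=float(rng.uniform(0, 2.5e-3)),
                    GLC_in=float(rng.uniform(5, 150)),
                    GLN_in=float(rng.uniform(1, 25)),
                    Xv_in=float(rng.uniform(1e8, 5e9)))
            for _ in range(n)]
    return FeedPolicy.equal_arcs(t_f, arcs)
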