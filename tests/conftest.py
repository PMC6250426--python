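import numpy as np
import pytest

import hamrule as hr


@pytest.fixture(scope="session")
def examples():
    """Worked n = 10 examples keyed by name."""
    return {e.name: e for e in hr.worked_examples()}


@pytest.fixture(scope="session")
def synergy_fitness():
    """2-player prisoner's dilemma with synergy (n = 2 fitness function)."""
    return hr.synergy_game().to_fitness()


@pytest.fixture(scope="session")
def antisynergy_fitness():
    """2-player prisoner's dilemma with anti-synergy."""
    return hr.antisynergy_game().to_fitness()


def random_fitness(rng, n):
    """A finite random fitness function on groups of size n."""
    return hr.FitnessFunction(n, rng.normal(2.0, 1.0, n), rng.normal(2.0, 1.0, n))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
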