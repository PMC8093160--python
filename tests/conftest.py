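import numpy as np
import pytest

from pgsnurture.sim import SimConfig, evolve, extract_trios, simulate_trios


@pytest.fixture(scope="session")
def central_4k():
    """Central scenario (equilibrium AM) at a reduced 4K-family size."""
    return SimConfig(n_fam=4000, seed=101)


@pytest.fixture(scope="session")
def noam_4k():
    """Central scenario without assortative mating."""
    return SimConfig(n_fam=4000, r_mate=0.0, seed=102)


@pytest.fixture(scope="session")
def diseq_4k():
    """VT at equilibrium, a single generation of assortative mating."""
    return SimConfig(n_fam=4000, generations=1, vt_burnin=19, seed=103)


@pytest.fixture(scope="session")
def evolved_central(central_4k):
    parents, offspring, cvs = evolve(central_4k)
    return parents, offspring, cvs


@pytest.fixture(scope="session")
def trios_central(evolved_central, central_4k):
    parents, offspring, _ = evolved_central
    rng = np.random.default_rng(7)
    return extract_trios(parents, offspring, central_4k.n_fam, rng)


@pytest.fixture(scope="session")
def trios_noam(noam_4k):
    return simulate_trios(noam_4k)
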