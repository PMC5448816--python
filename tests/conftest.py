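import pytest

from steadycom import fixtures as fx


@pytest.fixture(scope="session")
def single_toy():
    """One organism, uptake 10, yield 1: mu_max = 10."""
    return fx.make_single_organism_toy(uptake=10.0, biomass_yield=1.0)


@pytest.fixture(scope="session")
def atpm_toy():
    """Two identical organisms, uptake 4, ATPM demand 1: mu_max = 3."""
    return fx.make_atpm_toy(n=2, atpm_lb=1.0, uptake=4.0)


@pytest.fixture(scope="session")
def ring4():
    """Four obligate cross-feeders in a ring, substrate uptake 1: mu_max = 1."""
    return fx.make_auxotroph_ring(n=4, export_yield=1.5, uptake=1.0)


@pytest.fixture(scope="session")
def competitive_toy():
    """Two organisms competing for one substrate with equal yield."""
    return fx.build_toy(
        fx.ToySpec(
            n_organisms=2,
            yields={"org1": 1.0, "org2": 1.0},
            community_uptake={"s": 2.0},
        )
    )
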