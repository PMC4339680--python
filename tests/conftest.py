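import pytest

from netsim import figure1_fixture, random_fixture


@pytest.fixture(scope="session")
def fig1():
    return figure1_fixture()


@pytest.fixture(scope="session")
def small_random():
    """One modest random world reused across oracle checks."""
    return random_fixture(n_terms=15, n_genes=20, annot_density=0.12,
                          net_density=0.15, seed=42)


@pytest.fixture(scope="session")
def random_bundles():
    """A spread of seeded worlds for property checks."""
    return [
        random_fixture(n_terms=12, n_genes=15, annot_density=0.15,
                       net_density=0.2, seed=s)
        for s in range(5)
    ]
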