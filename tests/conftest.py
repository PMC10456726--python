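import random

import pytest

from samplemeta.fixtures import (
    FixtureConfig,
    default_store,
    generate_store,
    generate_vocabulary,
    species_rule_fixture,
    worked_example,
)


@pytest.fixture(scope="session")
def example():
    """The lung/ozone worked-example bundle."""
    return worked_example()


@pytest.fixture()
def store():
    """A fresh copy of the worked-example vocabulary store."""
    return default_store()


@pytest.fixture(scope="session")
def species_fixture():
    return species_rule_fixture()


@pytest.fixture(scope="session")
def big_vocab():
    """A generated 500-term species vocabulary with synonyms."""
    return generate_vocabulary("species", FixtureConfig(seed=7, n_terms=500))


@pytest.fixture()
def small_store():
    """A generated three-category store for pipeline property tests."""
    return generate_store(
        ["species", "organ", "drugName"], FixtureConfig(seed=3, n_terms=25)
    )


@pytest.fixture()
def rng():
    return random.Random(1234)
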