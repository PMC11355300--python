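import pytest

from aida import default_model, default_zone_scheme, generate_cohort, load_fixtures


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture(scope="session")
def scheme():
    return default_zone_scheme()


@pytest.fixture(scope="session")
def cohort135():
    """A study-sized synthetic cohort shared across tests."""
    return generate_cohort(n=135, seed=11)


@pytest.fixture(scope="session")
def cohort10k():
    """A large synthetic cohort for Monte-Carlo recovery checks."""
    return generate_cohort(n=10_000, seed=23)
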