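import pytest

from muftox import analyze, make_fixture


@pytest.fixture(scope="session")
def minimal_ds():
    """Small synthetic dataset covering every architecture and association class."""
    return make_fixture("minimal")


@pytest.fixture(scope="session")
def minimal_result(minimal_ds):
    return analyze(
        minimal_ds.genes,
        minimal_ds.hits,
        minimal_ds.regions,
        minimal_ds.genomes,
        minimal_ds.toxin_catalog,
    )


@pytest.fixture(scope="session")
def empty_ds():
    return make_fixture("empty")
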