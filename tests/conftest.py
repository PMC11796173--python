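import logging

import pytest

from armc5curate import (
    EngineConfig, load_packaged_germline, load_packaged_somatic,
)

# the curated-table loaders log every printed-vs-inferred contradiction;
# keep test output quiet but leave warnings capturable via caplog
logging.getLogger("armc5curate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def germline_all():
    """All rows of the packaged germline table (variants + polymorphisms)."""
    return load_packaged_germline()


@pytest.fixture(scope="session")
def germline(germline_all):
    """Curated germline variants, frequent polymorphisms excluded."""
    return [r for r in germline_all if not r.polymorphism]


@pytest.fixture(scope="session")
def somatic():
    return load_packaged_somatic()


@pytest.fixture(scope="session")
def strict_cfg():
    return EngineConfig(conflict_policy="strict")


@pytest.fixture(scope="session")
def curated_cfg():
    return EngineConfig(conflict_policy="as_curated")
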