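import pytest

from capa.patterns import default_library
from capa.synth import paper_candidates


@pytest.fixture(scope="session")
def lib():
    return default_library()


@pytest.fixture(scope="session")
def candidates():
    """The ten packaged candidate compounds, keyed by id."""
    return {row["id"]: row for row in paper_candidates()}
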