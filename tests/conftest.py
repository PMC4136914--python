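import pytest

from braincost.pipeline import estimate
from braincost.synthetic import evidence_fixture


@pytest.fixture(scope="session")
def evidence():
    """Bundled evidence table: (corpus, references, disorder configs)."""
    return evidence_fixture()


@pytest.fixture(scope="session")
def bundle(evidence):
    """Deterministic end-to-end estimate on the bundled evidence table."""
    corpus, refs, configs = evidence
    return estimate(corpus, refs, configs)
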