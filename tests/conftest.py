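import pytest

from crisiscomm import default_codebook
from crisiscomm.synthetic import SyntheticCorpusConfig, generate_corpus, paper_fixtures


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture(scope="session")
def fixtures():
    return paper_fixtures()


@pytest.fixture(scope="session")
def small_corpus():
    """Default-size synthetic corpus (72 posts, 11/54/7) with fixed seed."""
    return generate_corpus(SyntheticCorpusConfig(seed=20160827))
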