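import pytest

from nero.datasets import CorpusGenConfig, gen_corpus
from nero.ontology import load_ontology


@pytest.fixture(scope="session")
def onto():
    return load_ontology()


@pytest.fixture(scope="session")
def small_corpus(onto):
    """A 300-document synthetic corpus with its ground-truth record."""
    return gen_corpus(CorpusGenConfig(n_documents=300, seed=42), onto)
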