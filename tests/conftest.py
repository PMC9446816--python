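import pytest

from birelex.corpus import EntityMention, RelationInstance
from birelex.encoding import MARKER_TOKENS, WhitespaceTokenizer
from birelex.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture
def tokenizer():
    tok = WhitespaceTokenizer()
    tok.register_tokens(MARKER_TOKENS)
    return tok


@pytest.fixture
def simple_instance():
    """The canonical worked example: S="A activates B C", e1="A", e2="B C"."""
    return RelationInstance(
        pmid="PMID1",
        sent_id=0,
        sentence="A activates B C",
        entity1=EntityMention("A", 0, 1, "gene"),
        entity2=EntityMention("B C", 12, 15, "protein"),
        label="positive_cause",
    )


@pytest.fixture(scope="session")
def small_corpus():
    """120 deterministic synthetic (instance, cue) pairs."""
    return generate_corpus(GeneratorConfig(n_instances=120, seed=11))
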