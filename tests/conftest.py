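import pytest

from fcgppi.corpus_io import make_example, normalize_and_tokenize

TABLE1_SENTENCE = (
    "The results show that prot1 heterodimerizes with prot0 and prot2 in vivo , "
    "but it does not homodimerize to a measurable extent ."
)


@pytest.fixture(scope="session")
def table1_example():
    """The worked EDF example sentence: distance 5, one prot0 mention."""
    tokens = normalize_and_tokenize(TABLE1_SENTENCE)
    return make_example(tokens, "positive", example_id="example0", doc_id="doc0")


@pytest.fixture(scope="session")
def short_example():
    """prot1 interacts with prot2, plus minimal context."""
    return make_example(
        ["we", "show", "prot1", "interacts", "with", "prot2", "here", "."],
        "positive",
        example_id="ex-short",
        doc_id="doc1",
    )
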