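import networkx as nx
import pytest

from cointriage.corpus import Corpus, Document, EntityMention, Sentence
from cointriage.network import CooccurrenceNetwork

_CLASS_OF_PREFIX = {"c": "chemical", "g": "gene", "d": "disease"}


def make_sentence(index: int, *names: str) -> Sentence:
    """Build a tagged sentence from shorthand names like 'c1', 'g2', 'd1'.

    The leading letter encodes the entity class; mentions get consistent
    non-overlapping offsets inside a templated text.
    """
    words = []
    mentions = []
    pos = 0
    for name in names:
        cls = _CLASS_OF_PREFIX[name[0]]
        mentions.append(
            EntityMention(surface=name, entity_class=cls, start=pos, end=pos + len(name))
        )
        words.append(name)
        pos += len(name) + 1
    return Sentence(index=index, text=" ".join(words) + ".", mentions=mentions)


def make_doc(doc_id: str, *sentence_specs, query_id=None, label=None) -> Document:
    """A tagged document from tuples of shorthand names, one per sentence."""
    sentences = [make_sentence(i, *spec) for i, spec in enumerate(sentence_specs)]
    return Document(
        doc_id=doc_id,
        title="",
        body=" ".join(s.text for s in sentences),
        sentences=sentences,
        query_id=query_id,
        gold_label=label,
    )


@pytest.fixture
def toy_network() -> CooccurrenceNetwork:
    """The 5-article network with two bridging hub vertices (P2, P4)."""
    g = nx.Graph()
    g.add_edges_from(
        [("P1", "P2"), ("P2", "P3"), ("P2", "P4"), ("P3", "P4"), ("P4", "P5")]
    )
    return CooccurrenceNetwork(graph=g)


@pytest.fixture
def small_corpus() -> Corpus:
    """Four tagged documents in one query, with known pair structure."""
    return Corpus(
        documents=[
            make_doc("A", ("c1", "d1", "g1"), query_id="Q1", label=True),
            make_doc("B", ("c1", "d1"), ("c1", "d1"), query_id="Q1", label=True),
            make_doc("C", ("c2", "g1"), query_id="Q1", label=False),
            make_doc("D", (), query_id="Q1", label=False),
        ]
    )
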