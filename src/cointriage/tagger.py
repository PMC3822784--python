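"""Dictionary-based named entity tagging.

A generic stand-in for external gene / chemical / disease NER: each entity
class is described by a :class:`Lexicon` of normalized terms, and tagging is
case-insensitive longest-match-first scanning on token boundaries.  Users
with real NER output supply pre-tagged corpora instead and skip this stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .corpus import ENTITY_CLASSES, Document, EntityMention, Sentence, normalize_term

log = logging.getLogger(__name__)

# Cross-class ties at an identical span are broken by this fixed precedence,
# keeping runs reproducible in the face of ambiguous dictionaries.
CLASS_PRECEDENCE = {"chemical": 0, "gene": 1, "disease": 2}

# A token is a maximal run of alphanumerics; hyphens and all punctuation act
# as separators, so "urethane" cannot be matched by the entry "ane".
_ALNUM = str.isalnum


@dataclass
class Lexicon:
    """A set of normalized terms of one entity class."""

    entity_class: str
    entries: frozenset[str] = field(default_factory=frozenset)
    max_term_tokens: int = 0

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {self.entity_class!r}")

    def __contains__(self, term: str) -> bool:
        return term in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def build_lexicon(terms, entity_class: str) -> Lexicon:
    """Build a :class:`Lexicon` from raw term strings.

    Terms are normalized (lowercase, hyphens to spaces, whitespace
    collapsed) and deduplicated; empty strings are dropped.  Raises
    ``ValueError`` if no usable entries remain.
    """
    entries = set()
    for raw in terms:
        norm = normalize_term(raw.replace("-", " "))
        if norm:
            entries.add(norm)
    if not entries:
        raise ValueError(f"no usable {entity_class} lexicon entries")
    return Lexicon(
        entity_class=entity_class,
        entries=frozenset(entries),
        max_term_tokens=max(len(e.split()) for e in entries),
    )


def read_lexicon(path, entity_class: str) -> Lexicon:
    """Read a plain-text lexicon file (one term per line, UTF-8)."""
    with open(path, encoding="utf-8") as fh:
        return build_lexicon((line.rstrip("\n") for line in fh), entity_class)


def _tokenize(text: str) -> list[tuple[int, int, str]]:
    """Maximal alphanumeric runs as (start, end, lowercased token)."""
    tokens = []
    i, n = 0, len(text)
    while i < n:
        if _ALNUM(text[i]):
            j = i + 1
            while j < n and _ALNUM(text[j]):
                j += 1
            tokens.append((i, j, text[i:j].lower()))
            i = j
        else:
            i += 1
    return tokens


def tag_sentence(sentence: Sentence, lexicons: list[Lexicon]) -> Sentence:
    """Fill ``sentence.mentions`` by dictionary matching.

    Scans left to right over token boundaries, preferring the longest
    matching term at each position; matches never overlap.  When lexicons of
    different classes contain the same term, the precedence
    chemical > gene > disease applies and a warning is logged.
    """
    if not lexicons:
        sentence.mentions = []
        return sentence
    tokens = _tokenize(sentence.text)
    max_tokens = max(lx.max_term_tokens for lx in lexicons)
    lexicons = sorted(lexicons, key=lambda lx: CLASS_PRECEDENCE[lx.entity_class])

    mentions: list[EntityMention] = []
    t = 0
    while t < len(tokens):
        match = None
        # longest match first: try the widest token window at this position
        for width in range(min(max_tokens, len(tokens) - t), 0, -1):
            start = tokens[t][0]
            end = tokens[t + width - 1][1]
            candidate = " ".join(tok for _, _, tok in tokens[t : t + width])
            hits = [lx for lx in lexicons if candidate in lx.entries]
            if hits:
                if len(hits) > 1:
                    log.warning(
                        "term %r matches classes %s; keeping %r",
                        candidate,
                        [lx.entity_class for lx in hits],
                        hits[0].entity_class,
                    )
                match = (start, end, width, hits[0].entity_class, candidate)
                break
        if match:
            start, end, width, cls, norm = match
            # norm is the matched lexicon entry, so hyphen/space variants of
            # the same term share one normalized name
            mentions.append(
                EntityMention(
                    surface=sentence.text[start:end],
                    entity_class=cls,
                    start=start,
                    end=end,
                    norm=norm,
                )
            )
            t += width
        else:
            t += 1
    sentence.mentions = mentions
    return sentence


def tag_document(doc: Document, lexicons: list[Lexicon]) -> Document:
    """Tag every sentence of a (sentence-split) document."""
    for sent in doc.sentences:
        tag_sentence(sent, lexicons)
    return doc
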