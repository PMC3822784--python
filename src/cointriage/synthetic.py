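"""Seeded synthetic triage corpora.

Emulates the statistical structure of a curation triage benchmark: several
per-query article lists (one per target chemical) in which a curatable
minority of articles mentions gene/chemical/disease concept pairs at a
higher per-sentence rate than the non-curatable rest, and curatable
articles preferentially reuse pairs from a small shared "hot" pool — which
is what induces shared-pair edges, and hence higher centrality, among them.

Entity names come from fixed synthetic vocabularies (``GENE0001`` …,
``CHEM0001`` …, ``DIS0001`` …) inserted into templated sentences, so the
dictionary tagger recovers every mention exactly; generated documents also
carry their pre-tagged sentences so the tagging stage can be bypassed.
Text is deliberately not linguistically realistic.

All randomness flows from one ``numpy`` generator seeded from
``SynthConfig.seed``; identical configs produce byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .corpus import Corpus, Document, EntityMention, Sentence
from .tagger import Lexicon, build_lexicon


@dataclass
class SynthConfig:
    """Generator settings; defaults give a 3-query, 600-article benchmark."""

    n_queries: int = 3
    docs_per_query: int = 200
    frac_curatable: float = 0.3
    n_genes: int = 150
    n_chemicals: int = 100
    n_diseases: int = 120
    sentences_per_doc: tuple[int, int] = (4, 8)
    pair_rate_curatable: float = 0.9
    pair_rate_noncuratable: float = 0.3
    shared_pair_pool: int = 20
    pool_affinity: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_queries, self.docs_per_query, self.n_genes,
               self.n_chemicals, self.n_diseases) <= 0:
            raise ValueError("all counts must be positive")
        if not (0.0 < self.frac_curatable < 1.0):
            raise ValueError("frac_curatable must be in (0, 1)")
        if self.pair_rate_curatable < 0 or self.pair_rate_noncuratable < 0:
            raise ValueError("pair rates must be non-negative")
        if self.pair_rate_curatable < self.pair_rate_noncuratable:
            raise ValueError("pair_rate_curatable must be >= pair_rate_noncuratable")
        lo, hi = self.sentences_per_doc
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad sentences_per_doc range ({lo}, {hi})")
        if not (0.0 <= self.pool_affinity <= 1.0):
            raise ValueError("pool_affinity must be in [0, 1]")
        space = (self.n_chemicals * self.n_diseases
                 + self.n_chemicals * self.n_genes
                 + self.n_genes * self.n_diseases)
        if self.shared_pair_pool <= 0 or self.shared_pair_pool > space:
            raise ValueError(
                f"shared_pair_pool must be in [1, {space}] for these vocabularies"
            )


def vocabularies(cfg: SynthConfig) -> dict[str, list[str]]:
    """The fixed synthetic name lists per entity class."""
    return {
        "gene": [f"GENE{i + 1:04d}" for i in range(cfg.n_genes)],
        "chemical": [f"CHEM{i + 1:04d}" for i in range(cfg.n_chemicals)],
        "disease": [f"DIS{i + 1:04d}" for i in range(cfg.n_diseases)],
    }


def lexicons(cfg: SynthConfig) -> list[Lexicon]:
    """Lexicons matching the generator's vocabularies, for the tagger."""
    vocab = vocabularies(cfg)
    return [build_lexicon(terms, cls) for cls, terms in vocab.items()]


# cross-class combinations an event may draw: (class_a, class_b)
_PAIR_CLASSES = (("chemical", "disease"), ("chemical", "gene"), ("gene", "disease"))


def _draw_pair(rng: np.random.Generator, vocab: dict[str, list[str]]):
    """One uniform random cross-class name pair (classes by space size)."""
    sizes = np.array([len(vocab[a]) * len(vocab[b]) for a, b in _PAIR_CLASSES], float)
    which = rng.choice(len(_PAIR_CLASSES), p=sizes / sizes.sum())
    ca, cb = _PAIR_CLASSES[which]
    return (
        (vocab[ca][rng.integers(len(vocab[ca]))], ca),
        (vocab[cb][rng.integers(len(vocab[cb]))], cb),
    )


def _build_sentence(index: int, entities: list[tuple[str, str]]) -> Sentence:
    """Template a sentence around the given (name, class) entities.

    Offsets are computed while assembling the text so the emitted mentions
    are exact; re-tagging the text with the synthetic lexicons recovers
    the same mentions.
    """
    if not entities:
        return Sentence(index=index, text="No notable interaction was observed.")
    prefix = "We observed that "
    parts: list[str] = [prefix]
    pos = len(prefix)
    mentions: list[EntityMention] = []
    for i, (name, cls) in enumerate(entities):
        if i > 0:
            sep = " and "
            parts.append(sep)
            pos += len(sep)
        parts.append(name)
        mentions.append(
            EntityMention(surface=name, entity_class=cls, start=pos, end=pos + len(name))
        )
        pos += len(name)
    parts.append(" were associated in this model.")
    return Sentence(index=index, text="".join(parts), mentions=mentions)


def generate_corpus(cfg: SynthConfig) -> tuple[Corpus, dict]:
    """Generate a labeled synthetic corpus and a generation log.

    Per query, a fixed ``round(frac_curatable * docs_per_query)`` articles
    are curatable (positions shuffled).  Each sentence of a document draws
    a Poisson number of co-mention events at the class's pair rate; each
    event inserts one concept pair — for curatable articles from the
    query's hot pool with probability ``pool_affinity``, otherwise uniform
    over the full cross-class pair space.  The first generated sentence
    becomes the title, the rest the abstract, so that re-splitting and
    re-tagging the plain text reproduces the emitted pre-tagged sentences.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    vocab = vocabularies(cfg)
    lo, hi = cfg.sentences_per_doc

    docs: list[Document] = []
    n_cur = int(round(cfg.frac_curatable * cfg.docs_per_query))
    for q in range(cfg.n_queries):
        query_id = f"Q{q + 1:02d}"
        pool = [_draw_pair(rng, vocab) for _ in range(cfg.shared_pair_pool)]
        labels = np.zeros(cfg.docs_per_query, dtype=bool)
        labels[:n_cur] = True
        rng.shuffle(labels)
        for d in range(cfg.docs_per_query):
            curatable = bool(labels[d])
            rate = cfg.pair_rate_curatable if curatable else cfg.pair_rate_noncuratable
            n_sent = int(rng.integers(lo, hi + 1))
            sentences: list[Sentence] = []
            for s in range(n_sent):
                k = int(rng.poisson(rate))
                entities: list[tuple[str, str]] = []
                seen: set[str] = set()
                for _ in range(k):
                    if curatable and rng.random() < cfg.pool_affinity:
                        a, b = pool[rng.integers(len(pool))]
                    else:
                        a, b = _draw_pair(rng, vocab)
                    for name, ecls in (a, b):
                        if name not in seen:
                            seen.add(name)
                            entities.append((name, ecls))
                if k == 0 and rng.random() < 0.3:
                    # a lone mention: no pair arises from it
                    ecls = ("gene", "chemical", "disease")[rng.integers(3)]
                    entities = [(vocab[ecls][rng.integers(len(vocab[ecls]))], ecls)]
                sentences.append(_build_sentence(s, entities))
            doc = Document(
                doc_id=f"{query_id}-D{d + 1:04d}",
                query_id=query_id,
                gold_label=curatable,
                title=sentences[0].text,
                body=" ".join(s.text for s in sentences[1:]),
                sentences=sentences,
            )
            docs.append(doc)
    log = {"generator": "cointriage.synthetic", "seed": cfg.seed, "config": asdict(cfg)}
    return Corpus(documents=docs), log


def write_lexicon_files(cfg: SynthConfig, out_dir) -> dict[str, str]:
    """Write one plain-text lexicon file per entity class; returns paths."""
    import os

    paths = {}
    for cls, terms in vocabularies(cfg).items():
        path = os.path.join(str(out_dir), f"{cls}s.txt")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(terms) + "\n")
        paths[cls] = path
    return paths
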