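"""Sentence-level concept pairs and the normalized co-occurrence score.

A *concept pair* is two named entities of different classes (gene /
chemical / disease) occurring in the same sentence of a document, typed

* ``cd`` — chemical–disease,
* ``cg`` — chemical–gene,
* ``gd`` — gene–disease,

with ``gcd`` their total.  Pairs are formed between *distinct normalized
names* (not mention tokens): a pair is counted once per sentence in which
it appears and summed over sentences, which limits the overestimation that
repeated mentions of the same name would otherwise cause.

Per article, each pair-type count x is standardized within its group to
z = (x − μ) / S (sample standard deviation), and the *normalized
co-occurrence score* of the article is z_cd + z_cg + z_gd.  The
standardization population is the per-query article list by default, or the
whole corpus with ``grouping="global"``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus import Corpus, Document

PAIR_TYPES = ("cd", "cg", "gd")

# canonical slot order within a pair, per type: (first class, second class)
_CLASS_RANK = {"chemical": 0, "gene": 1, "disease": 2}
_TYPE_SLOTS = {
    ("chemical", "disease"): "cd",
    ("chemical", "gene"): "cg",
    ("gene", "disease"): "gd",
}


@dataclass(frozen=True, order=True)
class ConceptPair:
    """An unordered cross-class pair of normalized entity names.

    Stored canonically — ``a_norm`` is the name of the first class of the
    pair type (chemical for cd/cg, gene for gd) — so (x, y) == (y, x).
    """

    pair_type: str
    a_norm: str
    b_norm: str

    @classmethod
    def make(cls, norm1: str, class1: str, norm2: str, class2: str) -> "ConceptPair":
        """Build the canonical pair from two classed names; classes must differ."""
        if class1 == class2:
            raise ValueError(f"concept pair requires distinct classes, got {class1}")
        (na, ca), (nb, cb) = sorted(
            [(norm1, class1), (norm2, class2)], key=lambda t: _CLASS_RANK[t[1]]
        )
        ptype = _TYPE_SLOTS.get((ca, cb))
        if ptype is None:
            raise ValueError(f"unknown class combination ({ca}, {cb})")
        return cls(pair_type=ptype, a_norm=na, b_norm=nb)


@dataclass
class ArticleFeatures:
    """Per-article concept-pair counts and their standard scores."""

    doc_id: str
    query_id: Optional[str] = None
    gold_label: Optional[bool] = None
    cd_count: int = 0
    cg_count: int = 0
    gd_count: int = 0
    z_cd: float = 0.0
    z_cg: float = 0.0
    z_gd: float = 0.0
    pairs: Counter = field(default_factory=Counter)

    @property
    def gcd_count(self) -> int:
        return self.cd_count + self.cg_count + self.gd_count

    @property
    def z_total(self) -> float:
        """The normalized co-occurrence score: z_cd + z_cg + z_gd."""
        return self.z_cd + self.z_cg + self.z_gd

    def count(self, pair_type: str) -> int:
        return {"cd": self.cd_count, "cg": self.cg_count, "gd": self.gd_count}[pair_type]


def extract_pairs(doc: Document) -> Counter:
    """Extract the multiset of concept pairs of a tagged document.

    For each sentence, every unordered pair of distinct normalized names
    belonging to two different classes contributes once; the multiset count
    of a pair is the number of sentences containing it.
    """
    counts: Counter = Counter()
    for sent in doc.sentences:
        # distinct names per class within this sentence
        names = {(m.norm, m.entity_class) for m in sent.mentions}
        items = sorted(names)  # determinism under mention order
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (n1, c1), (n2, c2) = items[i], items[j]
                if c1 != c2:
                    counts[ConceptPair.make(n1, c1, n2, c2)] += 1
    return counts


def article_features(corpus: Corpus) -> list[ArticleFeatures]:
    """Compute cd/cg/gd counts (z-scores left at 0) for every document."""
    out = []
    for doc in corpus:
        pairs = extract_pairs(doc)
        feats = ArticleFeatures(
            doc_id=doc.doc_id, query_id=doc.query_id, gold_label=doc.gold_label, pairs=pairs
        )
        for pair, n in pairs.items():
            if pair.pair_type == "cd":
                feats.cd_count += n
            elif pair.pair_type == "cg":
                feats.cg_count += n
            else:
                feats.gd_count += n
        out.append(feats)
    return out


def zscore_normalize(
    features: list[ArticleFeatures], grouping: str = "per_query"
) -> list[ArticleFeatures]:
    """Fill z_cd / z_cg / z_gd in place and return the feature list.

    Within each group (per query by default, or the whole list with
    ``grouping="global"``), z = (x − μ) / S per pair type with S the sample
    standard deviation (n − 1 denominator).  Groups of size 1 and
    zero-variance groups yield z = 0 for that pair type, keeping scores
    finite.
    """
    if grouping not in ("per_query", "global"):
        raise ValueError(f"unknown grouping {grouping!r}")
    groups: dict[Optional[str], list[ArticleFeatures]] = {}
    for f in features:
        key = f.query_id if grouping == "per_query" else None
        groups.setdefault(key, []).append(f)
    for members in groups.values():
        for ptype, attr in (("cd", "z_cd"), ("cg", "z_cg"), ("gd", "z_gd")):
            x = np.array([m.count(ptype) for m in members], dtype=float)
            if len(x) < 2:
                z = np.zeros_like(x)
            else:
                s = x.std(ddof=1)
                z = np.zeros_like(x) if s == 0 else (x - x.mean()) / s
            for m, zi in zip(members, z):
                setattr(m, attr, float(zi))
    return features


FEATURE_CSV_HEADER = "doc_id,query_id,cd,cg,gd,gcd,z_cd,z_cg,z_gd,z_total"


def write_feature_csv(features: list[ArticleFeatures], path) -> None:
    """Write the per-article feature table CSV (fixed header order)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(FEATURE_CSV_HEADER + "\n")
        for f in features:
            fh.write(
                f"{f.doc_id},{f.query_id or ''},{f.cd_count},{f.cg_count},"
                f"{f.gd_count},{f.gcd_count},{f.z_cd:.10g},{f.z_cg:.10g},"
                f"{f.z_gd:.10g},{f.z_total:.10g}\n"
            )
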