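"""Corpus data model and I/O.

Articles are held as :class:`Document` objects carrying a title, an abstract
body, an optional gold curation label (curatable / not curatable) and an
optional query identifier (the target chemical whose ranked list the article
belongs to).  Documents are split into :class:`Sentence` objects, each of
which may carry gene / chemical / disease :class:`EntityMention` spans —
either produced by the dictionary tagger or supplied pre-tagged by an
external NER tool.

Supported on-disk formats:

* corpus JSONL — one JSON object per line, optionally with pre-tagged
  sentences (see :func:`read_corpus`);
* corpus TSV — ``doc_id, query_id, label, title, abstract`` (no pre-tags);
* ranked-list TSV — ``rank, doc_id, score, label``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

ENTITY_CLASSES = ("gene", "chemical", "disease")


class CorpusFormatError(ValueError):
    """Malformed corpus file (carries line number and offending field)."""


def normalize_term(s: str) -> str:
    """Normalize an entity surface form: lowercase, collapse whitespace."""
    return " ".join(s.lower().split())


@dataclass
class EntityMention:
    """A tagged entity span within one sentence.

    Offsets are 0-based, half-open character positions into the sentence
    text.  ``norm`` is the lowercased, whitespace-collapsed surface form.
    """

    surface: str
    entity_class: str
    start: int
    end: int
    norm: str = ""

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {self.entity_class!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid span [{self.start}, {self.end}) for {self.surface!r}"
            )
        if not self.norm:
            self.norm = normalize_term(self.surface)


@dataclass
class Sentence:
    index: int
    text: str
    mentions: list[EntityMention] = field(default_factory=list)

    def validate(self) -> None:
        """Check mention spans lie within the text and do not overlap."""
        last_end = -1
        for m in sorted(self.mentions, key=lambda m: m.start):
            if m.end > len(self.text):
                raise ValueError(
                    f"mention {m.surface!r} span [{m.start},{m.end}) exceeds "
                    f"sentence length {len(self.text)}"
                )
            if m.start < last_end:
                raise ValueError(f"overlapping mentions at offset {m.start}")
            last_end = m.end


@dataclass
class Document:
    doc_id: str
    title: str = ""
    body: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    gold_label: Optional[bool] = None
    query_id: Optional[str] = None

    @property
    def is_tagged(self) -> bool:
        return bool(self.sentences)


@dataclass
class Corpus:
    documents: list[Document] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusFormatError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)

    @property
    def queries(self) -> set[str]:
        return {d.query_id for d in self.documents if d.query_id is not None}

    def by_query(self) -> dict[Optional[str], list[Document]]:
        """Group documents by query_id, preserving document order."""
        groups: dict[Optional[str], list[Document]] = {}
        for doc in self.documents:
            groups.setdefault(doc.query_id, []).append(doc)
        return groups


# --- sentence splitting ------------------------------------------------------

# Split after '.', '!' or '?' when followed by whitespace.  Abbreviation
# handling is deliberately not attempted; adequate for abstracts and for
# synthetic text, and fully deterministic.
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")


def split_sentences(text: str) -> list[str]:
    """Split free text into sentence strings.

    Deterministic rule-based splitting: a sentence ends at '.', '!' or '?'
    followed by whitespace.  Empty segments are dropped; no characters other
    than the inter-sentence whitespace are lost.
    """
    if not text:
        return []
    parts = _SENT_BOUNDARY.split(text)
    return [p.strip() for p in parts if p.strip()]


def document_text(doc: Document, include_title: bool = True) -> str:
    """Concatenate title and body for splitting.

    With ``include_title`` (default) the title takes part in sentence-level
    pair extraction; a terminal '. ' is inserted after it unless the title
    already ends with a sentence terminator.
    """
    if not include_title or not doc.title:
        return doc.body
    title = doc.title.rstrip()
    if title and title[-1] not in ".!?":
        title += "."
    return f"{title} {doc.body}" if doc.body else title


def split_document(doc: Document, include_title: bool = True) -> Document:
    """Fill ``doc.sentences`` from title + body (mentions left empty)."""
    doc.sentences = [
        Sentence(index=i, text=t)
        for i, t in enumerate(split_sentences(document_text(doc, include_title)))
    ]
    return doc


# --- readers / writers -------------------------------------------------------


def _mention_from_json(obj: dict, lineno: int) -> EntityMention:
    try:
        return EntityMention(
            surface=obj["surface"],
            entity_class=obj["class"],
            start=int(obj["start"]),
            end=int(obj["end"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusFormatError(f"line {lineno}: bad mention record: {exc}") from exc


def _document_from_json(obj: dict, lineno: int) -> Document:
    for key in ("doc_id", "title", "abstract"):
        if key not in obj:
            raise CorpusFormatError(f"line {lineno}: missing field {key!r}")
    if not isinstance(obj["doc_id"], str) or not obj["doc_id"]:
        raise CorpusFormatError(f"line {lineno}: field 'doc_id' must be a non-empty string")
    doc = Document(
        doc_id=obj["doc_id"],
        title=obj["title"] or "",
        body=obj["abstract"] or "",
        gold_label=obj.get("label"),
        query_id=obj.get("query_id"),
    )
    if obj.get("sentences"):
        for i, s in enumerate(obj["sentences"]):
            if "text" not in s:
                raise CorpusFormatError(f"line {lineno}: sentence {i} missing 'text'")
            sent = Sentence(
                index=i,
                text=s["text"],
                mentions=[_mention_from_json(m, lineno) for m in s.get("mentions", [])],
            )
            try:
                sent.validate()
            except ValueError as exc:
                raise CorpusFormatError(f"line {lineno}: {exc}") from exc
            doc.sentences.append(sent)
    return doc


def read_corpus(path, format: str = "jsonl") -> Corpus:
    """Read a corpus file.

    ``format`` is ``jsonl`` (one object per line, pre-tagged sentences
    preserved when present) or ``tsv`` (``doc_id, query_id, label, title,
    abstract``; no pre-tags).  Documents are returned in file order.
    Malformed records raise :class:`CorpusFormatError` naming the line.
    """
    if format == "jsonl":
        return _read_jsonl(path)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown corpus format {format!r}")


def _read_jsonl(path) -> Corpus:
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(f"line {lineno}: invalid JSON: {exc}") from exc
            doc = _document_from_json(obj, lineno)
            if doc.doc_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return Corpus(documents=docs)


_TSV_NULL = {"", "null", "none", "na"}


def _read_tsv(path) -> Corpus:
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise CorpusFormatError(
                    f"line {lineno}: expected 5 tab-separated fields, got {len(parts)}"
                )
            doc_id, query_id, label, title, abstract = parts
            if not doc_id:
                raise CorpusFormatError(f"line {lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusFormatError(f"line {lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            lab: Optional[bool]
            if label.lower() in _TSV_NULL:
                lab = None
            elif label.lower() in {"1", "true"}:
                lab = True
            elif label.lower() in {"0", "false"}:
                lab = False
            else:
                raise CorpusFormatError(f"line {lineno}: bad label {label!r}")
            docs.append(
                Document(
                    doc_id=doc_id,
                    query_id=query_id if query_id.lower() not in _TSV_NULL else None,
                    gold_label=lab,
                    title=title,
                    body=abstract,
                )
            )
    return Corpus(documents=docs)


def _mention_to_json(m: EntityMention) -> dict:
    return {"surface": m.surface, "class": m.entity_class, "start": m.start, "end": m.end}


def write_corpus(corpus: Corpus, path, include_sentences: bool = True) -> None:
    """Write a corpus as JSONL; the inverse of :func:`read_corpus`."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            obj: dict = {
                "doc_id": doc.doc_id,
                "query_id": doc.query_id,
                "title": doc.title,
                "abstract": doc.body,
                "label": doc.gold_label,
            }
            if include_sentences and doc.sentences:
                obj["sentences"] = [
                    {"text": s.text, "mentions": [_mention_to_json(m) for m in s.mentions]}
                    for s in doc.sentences
                ]
            fh.write(json.dumps(obj, sort_keys=False) + "\n")


def write_ranked_tsv(entries: Iterable[tuple], path) -> None:
    """Write a ranked list as TSV with columns rank, doc_id, score, label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tdoc_id\tscore\tlabel\n")
        for rank, doc_id, score, label in entries:
            lab = "" if label is None else str(int(label))
            fh.write(f"{rank}\t{doc_id}\t{score:.10g}\t{lab}\n")


def read_ranked_tsv(path) -> list[tuple[int, str, float, Optional[bool]]]:
    """Read a ranked-list TSV written by :func:`write_ranked_tsv`."""
    out: list[tuple[int, str, float, Optional[bool]]] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["rank", "doc_id", "score", "label"]:
            raise CorpusFormatError(f"unexpected ranked-list header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise CorpusFormatError(f"line {lineno}: expected 4 fields")
            rank, doc_id, score, label = parts
            out.append(
                (int(rank), doc_id, float(score), bool(int(label)) if label else None)
            )
    return out
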