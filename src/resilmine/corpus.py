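"""Corpus data model, readers/writers and text preprocessing.

Every downstream stage (contrastive representation learning, phrase
extraction, screening) consumes the :class:`Corpus` / :class:`TokenSequence`
containers defined here.  Input corpora are plain JSONL (one article per
line) or CSV; preprocessing lowercases, splits sentences, tokenizes and
drops stop words and punctuation.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Document",
    "Corpus",
    "TokenSequence",
    "CorpusError",
    "DuplicateIdError",
    "load_default_stopwords",
    "read_corpus",
    "write_corpus",
    "preprocess",
    "preprocess_corpus",
]


class CorpusError(ValueError):
    """Malformed corpus input (missing fields, empty corpus, bad record)."""


class DuplicateIdError(CorpusError):
    """Raised when two documents share a doc_id; carries the offenders."""

    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate doc_id values: {sorted(set(self.duplicates))}")


@dataclass(frozen=True)
class Document:
    """One article: a unique id, a title and the body text."""

    doc_id: str
    title: str = ""
    body: str = ""
    year: int | None = None
    language: str | None = None

    def __post_init__(self) -> None:
        if not str(self.doc_id).strip():
            raise CorpusError("doc_id must be non-empty")
        if not str(self.body).strip():
            raise CorpusError(f"document {self.doc_id!r}: body empty after stripping")


@dataclass
class Corpus:
    """Ordered collection of documents with unique ids."""

    documents: list[Document]

    def __post_init__(self) -> None:
        if len(self.documents) == 0:
            raise CorpusError("a corpus must contain at least one document")
        seen: dict[str, int] = {}
        dups = []
        for d in self.documents:
            if d.doc_id in seen:
                dups.append(d.doc_id)
            seen[d.doc_id] = 1
        if dups:
            raise DuplicateIdError(dups)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    @property
    def n(self) -> int:
        return len(self.documents)


@dataclass
class TokenSequence:
    """Preprocessed document: lowercase content tokens plus sentence spans.

    ``sentences`` holds (start, stop) spans over ``tokens`` that partition the
    token list; the boundaries are found before stop-word removal so that the
    sentence-reordering augmentation has real sentences to permute.  A
    document whose tokens are all stop words is *flagged* empty rather than
    rejected.
    """

    doc_id: str
    tokens: list[str] = field(default_factory=list)
    sentences: list[tuple[int, int]] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return len(self.tokens) == 0

    def __len__(self) -> int:
        return len(self.tokens)


_FIELDS = ("doc_id", "title", "body", "year", "language")


def load_default_stopwords() -> frozenset[str]:
    text = resources.files("resilmine.data").joinpath("stopwords.txt").read_text("utf-8")
    return frozenset(w.strip() for w in text.splitlines() if w.strip())


def _doc_from_record(rec: dict, index: int) -> Document:
    for key in ("doc_id", "body"):
        if key not in rec or rec[key] in (None, ""):
            raise CorpusError(f"record {index}: missing required field {key!r}")
    year = rec.get("year")
    if year in ("", None):
        year = None
    else:
        year = int(year)
    return Document(
        doc_id=str(rec["doc_id"]),
        title=str(rec.get("title") or ""),
        body=str(rec["body"]),
        year=year,
        language=rec.get("language") or None,
    )


def read_corpus(path: str | Path, format: str = "jsonl") -> Corpus:
    """Read a corpus from JSONL or CSV, preserving record order.

    Raises :class:`CorpusError` on missing fields (with the record index),
    :class:`DuplicateIdError` listing repeated ids, and :class:`CorpusError`
    on an empty file.
    """
    path = Path(path)
    docs: list[Document] = []
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusError(f"record {i}: invalid JSON ({exc})") from exc
                docs.append(_doc_from_record(rec, i))
    elif format == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            for i, rec in enumerate(csv.DictReader(fh)):
                docs.append(_doc_from_record(rec, i))
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not docs:
        raise CorpusError(f"{path}: empty corpus")
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path, format: str = "jsonl") -> Path:
    """Write a corpus; ``read_corpus`` round-trips the JSONL dialect."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for d in corpus:
                rec = {
                    "doc_id": d.doc_id,
                    "title": d.title,
                    "body": d.body,
                    "year": d.year,
                    "language": d.language,
                }
                fh.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    elif format == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=list(_FIELDS))
            w.writeheader()
            for d in corpus:
                w.writerow(
                    {
                        "doc_id": d.doc_id,
                        "title": d.title,
                        "body": d.body,
                        "year": "" if d.year is None else d.year,
                        "language": d.language or "",
                    }
                )
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    return path


# Sentence splitting: terminal punctuation with a small abbreviation guard.
_ABBREVIATIONS = {"e.g", "i.e", "et al", "etc", "cf", "vs", "dr", "fig", "no", "approx"}
_SENT_BOUNDARY = re.compile(r"(?<=[.!?])\s+")
DEFAULT_TOKEN_PATTERN = r"[a-z0-9]+(?:[-'][a-z0-9]+)*|\[mask\]"
_TOKEN_RE = re.compile(DEFAULT_TOKEN_PATTERN)


def _split_sentences(text: str) -> list[str]:
    pieces = _SENT_BOUNDARY.split(text)
    merged: list[str] = []
    for piece in pieces:
        if merged:
            prev = merged[-1].rstrip()
            tail = ""
            if prev.endswith("."):
                parts = prev[:-1].rsplit(None, 1)
                tail = parts[-1].lower().strip(".") if parts and parts[-1] else ""
            if tail in _ABBREVIATIONS or (prev.endswith(".") and len(tail) == 1):
                merged[-1] = merged[-1] + " " + piece
                continue
        merged.append(piece)
    return [p for p in merged if p.strip()]


def preprocess(
    doc: Document,
    stopwords: Iterable[str] | None = None,
    token_pattern: str = DEFAULT_TOKEN_PATTERN,
) -> TokenSequence:
    """Lowercase, sentence-split, tokenize and drop stop words/punctuation.

    Sentence boundaries are recorded before stop-word removal; the returned
    spans partition the surviving token list (empty sentences are dropped).
    A document reduced to zero tokens comes back flagged empty, not as an
    exception.
    """
    stops = load_default_stopwords() if stopwords is None else frozenset(stopwords)
    tok_re = _TOKEN_RE if token_pattern == DEFAULT_TOKEN_PATTERN else re.compile(token_pattern)
    text = (doc.title + ". " + doc.body) if doc.title else doc.body
    tokens: list[str] = []
    spans: list[tuple[int, int]] = []
    for sent in _split_sentences(text.lower()):
        kept = [t for t in tok_re.findall(sent) if t not in stops]
        if kept:
            start = len(tokens)
            tokens.extend(kept)
            spans.append((start, len(tokens)))
    return TokenSequence(doc_id=doc.doc_id, tokens=tokens, sentences=spans)


def preprocess_corpus(
    corpus: Corpus, stopwords: Iterable[str] | None = None
) -> list[TokenSequence]:
    stops = load_default_stopwords() if stopwords is None else frozenset(stopwords)
    return [preprocess(d, stops) for d in corpus]
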