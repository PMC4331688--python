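"""Corpus input/output and exact-span evaluation.

Reads and writes the tab-separated dialects used by the BioCreative
CHEMDNER distribution: abstracts files (``doc_id  title  abstract``),
annotation/prediction span files (``doc_id  section  start  end  text
[type]``) and ranked CEM submission files (``doc_id  section:start:end
rank  confidence``).

Offsets are 0-based, end-exclusive, counted in Unicode code points within
the section string; title (``T``) and abstract (``A``) offsets are
independent of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

SECTIONS = ("T", "A")

SpanKey = tuple[str, str, int, int]


class CorpusFormatError(ValueError):
    """Raised on malformed corpus, annotation or prediction lines."""


@dataclass(frozen=True)
class Document:
    """One abstract record: identifier, title and body text."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def section_text(self, section: str) -> str:
        if section == "T":
            return self.title
        if section == "A":
            return self.abstract
        raise ValueError(f"unknown section code {section!r}")


@dataclass(frozen=True)
class EntityMention:
    """A gold or predicted entity span within one document section."""

    doc_id: str
    section: str
    start: int
    end: int
    text: str = ""
    entity_type: str | None = None

    def __post_init__(self) -> None:
        if self.section not in SECTIONS:
            raise ValueError(f"section must be one of {SECTIONS}, got {self.section!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span [{self.start}, {self.end})")

    @property
    def key(self) -> SpanKey:
        """The identity used for evaluation: (doc_id, section, start, end)."""
        return (self.doc_id, self.section, self.start, self.end)


@dataclass(frozen=True)
class EvaluationResult:
    """Micro-averaged exact-span counts and scores.

    Precision, recall and F1 use the 0/0 -> 0 convention so that an empty
    prediction set scores 0 rather than raising.
    """

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float = field(init=False, default=0.0)
    recall: float = field(init=False, default=0.0)
    f1: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        tp, fp, fn = self.true_positives, self.false_positives, self.false_negatives
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        object.__setattr__(self, "precision", p)
        object.__setattr__(self, "recall", r)
        object.__setattr__(self, "f1", f)

    def as_dict(self) -> dict[str, float]:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def read_abstracts(path: str | Path) -> list[Document]:
    """Read a tab-separated abstracts file into Documents.

    Each non-empty line carries exactly three tab-separated fields:
    ``doc_id``, ``title``, ``abstract``. Duplicate doc_ids are rejected.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(parts)}"
                )
            doc_id, title, abstract = parts
            if not doc_id:
                raise CorpusFormatError(f"{path}:{lineno}: empty doc_id")
            if doc_id in seen:
                raise CorpusFormatError(f"{path}:{lineno}: duplicate doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def write_abstracts(documents: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in documents:
            fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.abstract}\n")


def read_annotations(path: str | Path) -> list[EntityMention]:
    """Read a tab-separated span file into EntityMentions.

    Lines carry at least 5 fields: ``doc_id``, section (``T``/``A``),
    start, end, text, and an optional entity type.
    """
    mentions: list[EntityMention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected >=5 tab-separated fields, got {len(parts)}"
                )
            doc_id, section, start_s, end_s, text = parts[:5]
            entity_type = parts[5] if len(parts) > 5 and parts[5] else None
            if section not in SECTIONS:
                raise CorpusFormatError(f"{path}:{lineno}: unknown section {section!r}")
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: non-integer offsets") from exc
            if not (0 <= start < end):
                raise CorpusFormatError(
                    f"{path}:{lineno}: invalid span [{start}, {end})"
                )
            mentions.append(EntityMention(doc_id, section, start, end, text, entity_type))
    return mentions


def write_annotations(mentions: Iterable[EntityMention], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            typ = m.entity_type or ""
            fh.write(f"{m.doc_id}\t{m.section}\t{m.start}\t{m.end}\t{m.text}\t{typ}\n")


def write_predictions(
    scored: Iterable[tuple[EntityMention, float]], path: str | Path
) -> None:
    """Write a ranked CEM submission file.

    One line per mention: ``doc_id  section:start:end  rank  confidence``
    where rank is 1-based per document in descending confidence (ties
    broken by (section, start, end) lexicographic order) and confidence
    is printed with 5 decimal places.
    """
    by_doc: dict[str, list[tuple[EntityMention, float]]] = {}
    order: list[str] = []
    for mention, conf in scored:
        if not (0.0 <= conf <= 1.0):
            raise ValueError(f"confidence {conf} outside [0, 1]")
        if mention.doc_id not in by_doc:
            by_doc[mention.doc_id] = []
            order.append(mention.doc_id)
        by_doc[mention.doc_id].append((mention, conf))
    with open(path, "w", encoding="utf-8") as fh:
        for doc_id in order:
            ranked = sorted(
                by_doc[doc_id],
                key=lambda mc: (-mc[1], mc[0].section, mc[0].start, mc[0].end),
            )
            for rank, (m, conf) in enumerate(ranked, start=1):
                fh.write(f"{doc_id}\t{m.section}:{m.start}:{m.end}\t{rank}\t{conf:.5f}\n")


def read_predictions(path: str | Path) -> list[tuple[EntityMention, float]]:
    """Read a ranked CEM submission file back into (mention, confidence) pairs."""
    out: list[tuple[EntityMention, float]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CorpusFormatError(
                    f"{path}:{lineno}: expected 4 tab-separated fields"
                )
            doc_id, span, _rank, conf_s = parts
            try:
                section, start_s, end_s = span.split(":")
                mention = EntityMention(doc_id, section, int(start_s), int(end_s))
                conf = float(conf_s)
            except ValueError as exc:
                raise CorpusFormatError(f"{path}:{lineno}: malformed line") from exc
            out.append((mention, conf))
    return out


def evaluate_cem(
    gold: Iterable[EntityMention], predicted: Iterable[EntityMention]
) -> EvaluationResult:
    """Exact-span micro-averaged evaluation on (doc_id, section, start, end).

    Duplicate spans within either collection are collapsed; entity types
    are ignored — the CEM task scores spans, not subtypes.
    """
    gold_keys = {m.key for m in gold}
    pred_keys = {m.key for m in predicted}
    tp = len(gold_keys & pred_keys)
    return EvaluationResult(
        true_positives=tp,
        false_positives=len(pred_keys) - tp,
        false_negatives=len(gold_keys) - tp,
    )


def mentions_by_section(
    mentions: Iterable[EntityMention],
) -> dict[tuple[str, str], list[EntityMention]]:
    """Group mentions by (doc_id, section), sorted by start offset."""
    grouped: dict[tuple[str, str], list[EntityMention]] = {}
    for m in mentions:
        grouped.setdefault((m.doc_id, m.section), []).append(m)
    for key in grouped:
        grouped[key].sort(key=lambda m: (m.start, m.end))
    return grouped


def validate_offsets(
    documents: Sequence[Document], mentions: Iterable[EntityMention]
) -> list[EntityMention]:
    """Return mentions whose text does not match the document slice."""
    docs = {d.doc_id: d for d in documents}
    bad: list[EntityMention] = []
    for m in mentions:
        doc = docs.get(m.doc_id)
        if doc is None:
            bad.append(m)
            continue
        section = doc.section_text(m.section)
        if m.text and section[m.start : m.end] != m.text:
            bad.append(m)
    return bad
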