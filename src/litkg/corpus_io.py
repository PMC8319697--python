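"""Read/write PubTator corpora and sentence segmentation with stable offsets.

The PubTator exchange format stores one abstract per blank-line-separated
block::

    <pmid>|t|<title>
    <pmid>|a|<abstract>
    <pmid><TAB><start><TAB><end><TAB><text><TAB><type>[<TAB><norm id>]

All character offsets refer to the concatenation ``title + " " + abstract``
(PubTator's own convention) and are 0-based, half-open.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Sequence

#: The closed entity-type vocabulary used throughout the pipeline.
ENTITY_TYPES = (
    "Disease",
    "Symptom",
    "Chemical",
    "Drug",
    "CPM",
    "Herb",
    "Ingredient",
    "Gene",
    "Pathway",
)

#: Sentinel for a mention without a canonical database identifier.
UNNORMALIZED = "UNNORMALIZED"

# Common plural / long-form spellings seen in annotation exports.
_TYPE_ALIASES = {
    "Diseases": "Disease",
    "Symptoms": "Symptom",
    "Chemicals": "Chemical",
    "Drugs": "Drug",
    "Herbs": "Herb",
    "Ingredients": "Ingredient",
    "Genes": "Gene",
    "Pathways": "Pathway",
    "Chinese Patent medicine": "CPM",
    "Chinese Patent Medicine": "CPM",
}


class PubTatorError(ValueError):
    """Malformed PubTator input."""


class MentionValidationError(PubTatorError):
    """A mention span does not match the document text."""


def canonical_entity_type(label: str) -> str:
    """Map a type label (including plural aliases) onto the 9-type vocabulary."""
    label = label.strip()
    label = _TYPE_ALIASES.get(label, label)
    if label not in ENTITY_TYPES:
        raise PubTatorError(f"unknown entity type {label!r}")
    return label


@dataclass(frozen=True)
class EntityMention:
    """One typed entity mention, anchored by character span into full_text."""

    doc_pmid: str
    start: int
    end: int
    surface: str
    entity_type: str
    norm_id: str = UNNORMALIZED
    source: str = "preannotated"  # or "dictionary"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"mention span ({self.start}, {self.end}) is empty or reversed"
            )
        if not self.surface:
            raise ValueError("mention surface must be non-empty")
        if self.entity_type not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.entity_type!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _mention_sort_key(m: EntityMention) -> tuple:
    return (m.start, m.end, m.entity_type, m.norm_id)


@dataclass
class Document:
    """One abstract: title, abstract body, sentence spans and entity mentions.

    ``sentences`` holds (start, end) spans into :attr:`full_text`;
    ``flagged`` collects mentions that cross a sentence boundary (kept for
    inspection but excluded from relation extraction).
    """

    pmid: str
    title: str
    abstract: str
    sentences: list[tuple[int, int]] = field(default_factory=list)
    mentions: list[EntityMention] = field(default_factory=list)
    flagged: list[EntityMention] = field(default_factory=list)

    @property
    def full_text(self) -> str:
        return f"{self.title} {self.abstract}" if self.abstract else self.title

    def sentence_index_of(self, mention: EntityMention) -> int | None:
        """Index of the single sentence containing the mention, else None."""
        for i, (s, e) in enumerate(self.sentences):
            if mention.start >= s and mention.end <= e:
                return i
        return None

    def validate(self) -> None:
        """Check span and containment invariants; raise on violation."""
        text = self.full_text
        prev_end = 0
        for s, e in self.sentences:
            if not (0 <= s < e <= len(text)):
                raise MentionValidationError(
                    f"{self.pmid}: sentence span ({s}, {e}) outside document"
                )
            if s < prev_end:
                raise MentionValidationError(
                    f"{self.pmid}: overlapping/unsorted sentence spans"
                )
            prev_end = e
        for m in self.mentions:
            if m.end > len(text) or text[m.start : m.end] != m.surface:
                raise MentionValidationError(
                    f"{self.pmid}: mention span ({m.start}, {m.end}) does not "
                    f"match surface {m.surface!r}"
                )
            if self.sentences and self.sentence_index_of(m) is None:
                raise MentionValidationError(
                    f"{self.pmid}: mention at ({m.start}, {m.end}) crosses a "
                    "sentence boundary (should be flagged)"
                )


def _as_lines(source: str | IO[str] | Iterable[str]) -> Iterator[str]:
    if isinstance(source, str):
        yield from io.StringIO(source)
    else:
        yield from source


def read_pubtator(source: str | IO[str] | Iterable[str]) -> list[Document]:
    """Parse a PubTator stream (text, handle or line iterable) into Documents.

    Annotation lines become mentions with ``source="preannotated"``; offsets
    are validated against the title+space+abstract concatenation.
    """
    docs: list[Document] = []
    title: str | None = None
    abstract = ""
    pmid: str | None = None
    mentions: list[tuple] = []

    def flush(lineno: int) -> None:
        nonlocal title, abstract, pmid, mentions
        if pmid is None:
            return
        if title is None:
            raise PubTatorError(f"line {lineno}: block for {pmid} has no title line")
        doc = Document(pmid=pmid, title=title, abstract=abstract)
        text = doc.full_text
        for start, end, surface, etype, norm in mentions:
            if end > len(text) or text[start:end] != surface:
                raise MentionValidationError(
                    f"{pmid}: annotation span ({start}, {end}) does not match "
                    f"text {surface!r}"
                )
            doc.mentions.append(
                EntityMention(pmid, start, end, surface, etype, norm, "preannotated")
            )
        doc.mentions.sort(key=_mention_sort_key)
        docs.append(doc)
        title, abstract, pmid, mentions = None, "", None, []

    lineno = 0
    for lineno, raw in enumerate(_as_lines(source), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            flush(lineno)
            continue
        if "\t" not in line and ("|t|" in line or "|a|" in line):
            head, _, rest = line.partition("|")
            kind, _, text = rest.partition("|")
            if kind not in ("t", "a") or not head:
                raise PubTatorError(f"line {lineno}: malformed header line {line!r}")
            if pmid is not None and head != pmid:
                flush(lineno)
            pmid = head
            if kind == "t":
                title = text
            else:
                abstract = text
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise PubTatorError(
                f"line {lineno}: expected >=5 tab-separated fields, got {len(fields)}"
            )
        mid, start_s, end_s, surface, etype = fields[:5]
        norm = fields[5] if len(fields) > 5 and fields[5] else UNNORMALIZED
        if pmid is None or mid != pmid:
            raise PubTatorError(
                f"line {lineno}: annotation pmid {mid!r} outside block for {pmid!r}"
            )
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise PubTatorError(f"line {lineno}: non-integer offsets") from exc
        mentions.append((start, end, surface, canonical_entity_type(etype), norm))
    flush(lineno + 1)
    return docs


def write_pubtator(docs: Sequence[Document], stream: IO[str] | None = None) -> str:
    """Serialize documents canonically (mentions sorted by span, then type).

    Returns the serialized text; also writes to ``stream`` when given.
    """
    chunks: list[str] = []
    for doc in docs:
        doc.validate()
        chunks.append(f"{doc.pmid}|t|{doc.title}\n{doc.pmid}|a|{doc.abstract}\n")
        for m in sorted(doc.mentions, key=_mention_sort_key):
            norm = "" if m.norm_id == UNNORMALIZED else m.norm_id
            chunks.append(
                f"{m.doc_pmid}\t{m.start}\t{m.end}\t{m.surface}\t{m.entity_type}"
                + (f"\t{norm}\n" if norm else "\n")
            )
        chunks.append("\n")
    text = "".join(chunks)
    if stream is not None:
        stream.write(text)
    return text


# ---------------------------------------------------------------------------
# Sentence segmentation

# Tokens before a period that do NOT end a sentence.
_ABBREVIATIONS = frozenset(
    "e.g i.e cf vs etc al et fig figs eq ref refs approx ca dr mr mrs ms".split()
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")


def default_sentence_splitter(text: str) -> list[tuple[int, int]]:
    """Rule-based splitter: ., ! or ? followed by whitespace ends a sentence
    unless the preceding word is a known abbreviation. Spans are trimmed to
    non-whitespace and jointly cover all non-whitespace text.
    """
    breaks = []
    for match in _BOUNDARY_RE.finditer(text):
        word = re.search(r"(\S+)$", text[: match.start()])
        if word and word.group(1).rstrip(".").casefold() in _ABBREVIATIONS:
            continue
        breaks.append(match.end())
    if not breaks or breaks[-1] < len(text):
        breaks.append(len(text))
    spans = []
    prev = 0
    for b in breaks:
        seg = text[prev:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((prev + lead, b - trail))
        prev = b
    return spans


def split_sentences(doc: Document, splitter=None) -> Document:
    """Return a copy of ``doc`` with sentence spans computed and mentions
    re-checked for single-sentence containment.

    Mentions crossing a boundary are moved to ``doc.flagged`` (kept for
    diagnostics, excluded from relation extraction). Always succeeds.
    """
    splitter = splitter or default_sentence_splitter
    out = Document(pmid=doc.pmid, title=doc.title, abstract=doc.abstract)
    out.sentences = splitter(doc.full_text)
    for m in list(doc.mentions) + list(doc.flagged):
        if out.sentence_index_of(m) is None:
            out.flagged.append(m)
        else:
            out.mentions.append(m)
    out.mentions.sort(key=_mention_sort_key)
    return out
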