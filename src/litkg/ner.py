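"""Dictionary-based entity tagging plus the corpus-level frequency filter.

Tagging is longest-match over normalized token sequences, per sentence and
per entity type; within one type overlapping matches resolve longest-first,
then leftmost. Mentions ingested from upstream taggers (``source=
"preannotated"``) are preserved untouched and bypass the dictionaries, but —
like dictionary mentions — are subject to the corpus frequency filter:
entities mentioned fewer than ``min_entity_count`` times across the corpus
are routed to a manual-review list instead of the kept set, mirroring the
manual triage of rare entities in small literature corpora.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

from .corpus_io import Document, EntityMention, UNNORMALIZED
from .lexicon import Lexicon, normalize_surface, tokenize_with_offsets


@dataclass
class NerConfig:
    min_entity_count: int = 3
    case_sensitive: bool = False
    whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.min_entity_count < 1:
            raise ValueError("min_entity_count must be >= 1")


def census_key(mention: EntityMention) -> str:
    """Aggregation key for the frequency filter: the canonical id, or a
    surface-derived key for unnormalized mentions."""
    if mention.norm_id != UNNORMALIZED:
        return mention.norm_id
    return f"UNNORM:{mention.entity_type}:{normalize_surface(mention.surface)}"


def tag_document(
    doc: Document,
    lexicons: Mapping[str, Lexicon] | Sequence[Lexicon],
    config: NerConfig | None = None,
) -> Document:
    """Return a copy of ``doc`` with dictionary mentions added.

    Requires sentence spans (tag after :func:`litkg.corpus_io.split_sentences`).
    Cross-type overlaps are all emitted (one mention per type); exact
    duplicates of an existing (span, type) mention are not re-added.
    """
    config = config or NerConfig()
    if isinstance(lexicons, Mapping):
        lexicons = [lexicons[t] for t in sorted(lexicons)]
    else:
        lexicons = sorted(lexicons, key=lambda l: l.entity_type)
    out = Document(
        pmid=doc.pmid,
        title=doc.title,
        abstract=doc.abstract,
        sentences=list(doc.sentences),
        mentions=list(doc.mentions),
        flagged=list(doc.flagged),
    )
    text = out.full_text
    seen = {(m.start, m.end, m.entity_type) for m in out.mentions}
    for sent_start, sent_end in out.sentences or [(0, len(text))]:
        tokens = tokenize_with_offsets(text[sent_start:sent_end])
        keys = [t[0].casefold() for t in tokens]
        for lex in lexicons:
            if not lex.max_key_len:
                continue
            i = 0
            while i < len(tokens):
                hit = None
                for length in range(min(lex.max_key_len, len(tokens) - i), 0, -1):
                    cid = lex.lookup_key(tuple(keys[i : i + length]))
                    if cid is not None:
                        hit = (length, cid)
                        break
                if hit is None:
                    i += 1
                    continue
                length, cid = hit
                start = sent_start + tokens[i][1]
                end = sent_start + tokens[i + length - 1][2]
                surface = text[start:end]
                if config.case_sensitive and not any(
                    surface == s for s in lex.entries[cid].surfaces
                ):
                    i += length
                    continue
                if (start, end, lex.entity_type) not in seen:
                    out.mentions.append(
                        EntityMention(
                            out.pmid, start, end, surface,
                            lex.entity_type, cid, "dictionary",
                        )
                    )
                    seen.add((start, end, lex.entity_type))
                i += length
    out.mentions.sort(key=lambda m: (m.start, m.end, m.entity_type, m.norm_id))
    return out


@dataclass
class EntityCensus:
    """Corpus-wide mention and document counts per canonical entity."""

    mention_counts: Counter = field(default_factory=Counter)
    doc_counts: Counter = field(default_factory=Counter)
    example_pmid: dict[str, str] = field(default_factory=dict)
    example_surface: dict[str, str] = field(default_factory=dict)

    def items(self) -> list[tuple[str, int]]:
        """(key, mention count) sorted by count desc then key asc."""
        return sorted(self.mention_counts.items(), key=lambda kv: (-kv[1], kv[0]))

    @property
    def total(self) -> int:
        return sum(self.mention_counts.values())


def build_census(corpus: Iterable[Document]) -> EntityCensus:
    """Count mentions (all sources) per canonical entity across the corpus."""
    census = EntityCensus()
    for doc in corpus:
        keys_in_doc = set()
        for m in doc.mentions:
            key = census_key(m)
            census.mention_counts[key] += 1
            keys_in_doc.add(key)
            census.example_pmid.setdefault(key, doc.pmid)
            census.example_surface.setdefault(key, m.surface)
        for key in keys_in_doc:
            census.doc_counts[key] += 1
    return census


def apply_frequency_filter(
    corpus: Sequence[Document],
    census: EntityCensus,
    config: NerConfig | None = None,
) -> tuple[list[Document], list[EntityMention]]:
    """Partition mentions into kept documents and a review list.

    An entity whose corpus count is below ``min_entity_count`` has *all* its
    mentions routed to the review list unless its key is whitelisted. The
    kept and review sets partition the input mentions exactly.
    """
    config = config or NerConfig()
    kept_docs: list[Document] = []
    review: list[EntityMention] = []
    for doc in corpus:
        kept = Document(
            pmid=doc.pmid,
            title=doc.title,
            abstract=doc.abstract,
            sentences=list(doc.sentences),
            flagged=list(doc.flagged),
        )
        for m in doc.mentions:
            key = census_key(m)
            if (
                census.mention_counts[key] >= config.min_entity_count
                or key in config.whitelist
            ):
                kept.mentions.append(m)
            else:
                review.append(m)
        kept_docs.append(kept)
    return kept_docs, review


def write_review_tsv(
    census: EntityCensus,
    review: Sequence[EntityMention],
    stream: IO[str],
) -> None:
    """Serialize the review list for manual inspection (one row per entity)."""
    stream.write("canonical_id\tsurface\tcount\texample_pmid\n")
    seen = set()
    for m in sorted(review, key=lambda m: (census_key(m), m.doc_pmid, m.start)):
        key = census_key(m)
        if key in seen:
            continue
        seen.add(key)
        stream.write(
            f"{key}\t{census.example_surface.get(key, m.surface)}\t"
            f"{census.mention_counts[key]}\t{census.example_pmid.get(key, m.doc_pmid)}\n"
        )


def read_whitelist(source: str | IO[str] | Iterable[str]) -> frozenset[str]:
    """One canonical id per line; blank lines and ``#`` comments ignored."""
    lines = source.splitlines() if isinstance(source, str) else source
    return frozenset(
        s.strip() for s in lines if s.strip() and not s.lstrip().startswith("#")
    )
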