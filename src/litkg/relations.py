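"""Relation extraction: co-occurrence candidates, keyword-rule typing,
and corpus-level confidence aggregation.

The cascade mirrors standard sentence-level literature mining: (1) any two
typed entity mentions in one sentence whose type pair is an allowed family
form a candidate; (2) a keyword rulebook assigns a relation type from
trigger words found in the sentence (stemmed token/phrase matching, with the
high-noise triggers "and"/"between"/"no" restricted to the span between the
two entities); (3) sentence-level evidence for each entity pair is pooled
and the pair is kept as an edge when its majority relation type has enough
support and a high enough majority fraction ("confidence").

A pluggable classifier hook covers the sentences where no keyword fires
(the slot a trained sentence classifier such as a fine-tuned BioBERT would
occupy); the rule result always takes precedence when a keyword matched.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from importlib import resources
from typing import Callable, Iterable, Sequence

import yaml

from .corpus_io import Document, EntityMention
from .lexicon import tokenize_with_offsets


class RulebookError(ValueError):
    """Missing family or malformed rulebook."""


class PluginContractError(ValueError):
    """A plugin classifier returned a type outside the family's set."""


# ---------------------------------------------------------------------------
# Light stemming.  Both keywords and sentence tokens pass through the same
# function, so inflected trigger words ("treating", "demonstrated") match
# their other inflections.  Final -e is folded so "cure"/"cured" agree.

def stem(token: str) -> str:
    t = token.casefold()
    if len(t) > 4 and t.endswith("ies"):
        t = t[:-3] + "y"
    elif len(t) > 3 and t.endswith("es") and not t.endswith(("aes", "ees", "oes")):
        t = t[:-1]
    if len(t) > 3 and t.endswith("s") and not t.endswith(("ss", "us", "is")):
        t = t[:-1]
    if len(t) > 4 and t.endswith("ing"):
        t = t[:-3]
    elif len(t) > 3 and t.endswith("ed"):
        t = t[:-2]
    if len(t) > 3 and t.endswith("e"):
        t = t[:-1]
    return t


def _phrase_stems(phrase: str) -> tuple[str, ...]:
    return tuple(stem(tok) for tok in re.findall(r"[^\W_]+", phrase))


# ---------------------------------------------------------------------------
# Rulebook and pair schema

@dataclass(frozen=True)
class RelationRule:
    relation_type: str
    priority: int
    keywords: tuple[str, ...]
    keyword_stems: tuple[tuple[str, ...], ...]


@dataclass
class RuleBook:
    """Keyword rules per family group plus the family -> group schema."""

    groups: dict[str, list[RelationRule]]
    fallback: dict[str, str]
    families: dict[tuple[str, str], str]  # ordered (type_a, type_b) -> group
    between_only: frozenset[str] = frozenset()
    match_mode: str = "stem"

    def family_of(self, type_a: str, type_b: str) -> tuple[str, str] | None:
        """Canonical (ordered) family for a type pair, or None if disallowed."""
        if (type_a, type_b) in self.families:
            return (type_a, type_b)
        if (type_b, type_a) in self.families:
            return (type_b, type_a)
        return None

    def family_name(self, family: tuple[str, str]) -> str:
        return f"{family[0]}-{family[1]}"

    def rules_for(self, family: tuple[str, str]) -> list[RelationRule]:
        group = self.families.get(family)
        if group is None:
            raise RulebookError(f"family {self.family_name(family)} not in rulebook")
        return self.groups[group]

    def fallback_for(self, family: tuple[str, str]) -> str:
        return self.fallback[self.families[family]]

    def type_set(self, family: tuple[str, str]) -> set[str]:
        return {r.relation_type for r in self.rules_for(family)} | {
            self.fallback_for(family)
        }

    def type_priority(self, family: tuple[str, str]) -> dict[str, int]:
        """Priority rank per type (fallback last) for deterministic ties."""
        prio = {r.relation_type: r.priority for r in self.rules_for(family)}
        prio.setdefault(self.fallback_for(family), len(prio))
        return prio


def load_rulebook(source: str | None = None) -> RuleBook:
    """Load a rulebook YAML; with no argument, the packaged default rules."""
    if source is None:
        text = resources.files("litkg").joinpath("rules_default.yaml").read_text()
    else:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    data = yaml.safe_load(text)
    groups: dict[str, list[RelationRule]] = {}
    fallback: dict[str, str] = {}
    for gname, gdef in data["groups"].items():
        fallback[gname] = gdef.get("fallback", "other")
        rules = []
        for prio, tdef in enumerate(gdef["types"]):
            kws = tuple(str(k) for k in tdef.get("keywords", ()))
            rules.append(
                RelationRule(
                    relation_type=str(tdef["name"]),
                    priority=prio,
                    keywords=kws,
                    keyword_stems=tuple(_phrase_stems(k) for k in kws),
                )
            )
        groups[gname] = rules
    families: dict[tuple[str, str], str] = {}
    for fam, gname in data["families"].items():
        ta, _, tb = fam.partition("-")
        if gname not in groups:
            raise RulebookError(f"family {fam} references unknown group {gname}")
        families[(ta, tb)] = gname
    return RuleBook(
        groups=groups,
        fallback=fallback,
        families=families,
        between_only=frozenset(data.get("between_only", ())),
        match_mode=data.get("match_mode", "stem"),
    )


def default_rulebook() -> RuleBook:
    return load_rulebook(None)


# ---------------------------------------------------------------------------
# Candidates and evidence

@dataclass(frozen=True)
class Candidate:
    pmid: str
    sent_index: int
    mention_a: EntityMention
    mention_b: EntityMention
    family: tuple[str, str]


@dataclass(frozen=True)
class RelationEvidence:
    pmid: str
    sent_index: int
    mention_a: EntityMention
    mention_b: EntityMention
    family: tuple[str, str]
    relation_type: str
    matched_keyword: str | None
    classifier: str = "rule"  # or "plugin"


def extract_cooccurrence(doc: Document, rulebook: RuleBook) -> list[Candidate]:
    """All within-sentence mention pairs whose type pair is an allowed family.

    Self-pairs (same canonical id) and pairs of overlapping spans (one
    surface double-tagged under two types) are excluded; mentions flagged as
    crossing sentence boundaries never enter (they are not in doc.mentions).
    """
    by_sentence: dict[int, list[EntityMention]] = defaultdict(list)
    for m in doc.mentions:
        idx = doc.sentence_index_of(m)
        if idx is not None:
            by_sentence[idx].append(m)
    out: list[Candidate] = []
    for idx in sorted(by_sentence):
        ms = by_sentence[idx]
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                a, b = ms[i], ms[j]
                if a.norm_id == b.norm_id:
                    continue
                if a.start < b.end and b.start < a.end:  # overlapping spans
                    continue
                family = rulebook.family_of(a.entity_type, b.entity_type)
                if family is None:
                    continue
                if a.entity_type != family[0]:
                    a, b = b, a
                out.append(Candidate(doc.pmid, idx, a, b, family))
    return out


def _find_phrase(
    stems: Sequence[str], phrase: tuple[str, ...]
) -> list[int]:
    n = len(phrase)
    return [
        i
        for i in range(len(stems) - n + 1)
        if tuple(stems[i : i + n]) == phrase
    ]


def classify_pair(
    candidate: Candidate,
    sentence_text: str,
    sentence_start: int,
    rulebook: RuleBook,
) -> RelationEvidence:
    """Assign a relation type from the first (priority-ordered) keyword set
    with a hit in the sentence; no hit yields the family's fallback type.

    ``sentence_text`` is the sentence slice of the document's full text and
    ``sentence_start`` its offset, so keyword positions can be compared with
    the entity spans for the between-only triggers.
    """
    tokens = tokenize_with_offsets(sentence_text)
    stems = [stem(t[0]) for t in tokens]
    a, b = candidate.mention_a, candidate.mention_b
    gap_lo = min(a.end, b.end) - sentence_start
    gap_hi = max(a.start, b.start) - sentence_start
    for rule in rulebook.rules_for(candidate.family):
        for kw, kw_stems in zip(rule.keywords, rule.keyword_stems):
            if not kw_stems:
                continue
            hits = _find_phrase(stems, kw_stems)
            if kw.casefold() in rulebook.between_only:
                hits = [
                    i
                    for i in hits
                    if tokens[i][1] >= gap_lo
                    and tokens[i + len(kw_stems) - 1][2] <= gap_hi
                ]
            if hits:
                return RelationEvidence(
                    candidate.pmid,
                    candidate.sent_index,
                    a,
                    b,
                    candidate.family,
                    rule.relation_type,
                    kw,
                    "rule",
                )
    return RelationEvidence(
        candidate.pmid,
        candidate.sent_index,
        a,
        b,
        candidate.family,
        rulebook.fallback_for(candidate.family),
        None,
        "rule",
    )


def classify_document(
    doc: Document,
    rulebook: RuleBook,
    plugin: Callable[[str, Candidate], str] | None = None,
) -> list[RelationEvidence]:
    """Run candidate extraction + classification over one document.

    ``plugin`` (if given) classifies only the candidates the rules left at
    the fallback type — the rule's answer wins whenever a keyword matched.
    """
    text = doc.full_text
    out = []
    for cand in extract_cooccurrence(doc, rulebook):
        s, e = doc.sentences[cand.sent_index]
        ev = classify_pair(cand, text[s:e], s, rulebook)
        if plugin is not None and ev.matched_keyword is None:
            label = plugin(text[s:e], cand)
            if label not in rulebook.type_set(cand.family):
                raise PluginContractError(
                    f"plugin returned {label!r}, not in "
                    f"{sorted(rulebook.type_set(cand.family))} for family "
                    f"{rulebook.family_name(cand.family)}"
                )
            ev = RelationEvidence(
                ev.pmid, ev.sent_index, ev.mention_a, ev.mention_b,
                ev.family, label, None, "plugin",
            )
        out.append(ev)
    return out


def extract_relations(
    corpus: Iterable[Document],
    rulebook: RuleBook,
    plugin: Callable[[str, Candidate], str] | None = None,
) -> list[RelationEvidence]:
    """Sentence-level evidence for a whole corpus."""
    out = []
    for doc in corpus:
        out.extend(classify_document(doc, rulebook, plugin))
    return out


# ---------------------------------------------------------------------------
# Aggregation

@dataclass
class AggregatedRelation:
    """One corpus-level candidate edge for an entity pair within a family."""

    entity_a: str
    entity_b: str
    family: tuple[str, str]
    type_counts: dict[str, int]
    n: int
    majority_type: str
    confidence: float
    support: int
    pmids: frozenset[str]
    keywords: frozenset[str]

    @property
    def family_name(self) -> str:
        return f"{self.family[0]}-{self.family[1]}"


def aggregate(
    evidences: Iterable[RelationEvidence],
    rulebook: RuleBook,
    min_support: int = 2,
    confidence_threshold: float = 0.5,
) -> tuple[list[AggregatedRelation], list[AggregatedRelation]]:
    """Pool evidence per (entity_a, entity_b, family) and threshold.

    Confidence is the majority fraction over all co-occurrence sentences of
    the pair; fallback-type evidence counts toward the denominator but can
    only be the majority when no typed evidence exists. A pair survives when
    ``support >= min_support`` and ``confidence > confidence_threshold``
    (strict). Returns (kept, dropped).
    """
    grouped: dict[tuple, list[RelationEvidence]] = defaultdict(list)
    for ev in evidences:
        grouped[(ev.mention_a.norm_id, ev.mention_b.norm_id, ev.family)].append(ev)
    kept, dropped = [], []
    for (id_a, id_b, family) in sorted(grouped, key=lambda k: (k[0], k[1], k[2])):
        evs = grouped[(id_a, id_b, family)]
        counts = Counter(ev.relation_type for ev in evs)
        n = len(evs)
        prio = rulebook.type_priority(family)
        fb = rulebook.fallback_for(family)
        typed = {t: c for t, c in counts.items() if t != fb}
        pool = typed or dict(counts)
        majority = min(pool, key=lambda t: (-pool[t], prio.get(t, len(prio)), t))
        support = counts[majority]
        rel = AggregatedRelation(
            entity_a=id_a,
            entity_b=id_b,
            family=family,
            type_counts=dict(counts),
            n=n,
            majority_type=majority,
            confidence=support / n,
            support=support,
            pmids=frozenset(ev.pmid for ev in evs),
            keywords=frozenset(
                ev.matched_keyword for ev in evs if ev.matched_keyword
            ),
        )
        if rel.support >= min_support and rel.confidence > confidence_threshold:
            kept.append(rel)
        else:
            dropped.append(rel)
    return kept, dropped


def write_evidence_tsv(evidences: Sequence[RelationEvidence], stream) -> None:
    stream.write(
        "pmid\tsent_index\tid_a\tid_b\tfamily\tkeyword\trelation_type\tclassifier\n"
    )
    for ev in evidences:
        stream.write(
            f"{ev.pmid}\t{ev.sent_index}\t{ev.mention_a.norm_id}\t"
            f"{ev.mention_b.norm_id}\t{ev.family[0]}-{ev.family[1]}\t"
            f"{ev.matched_keyword or ''}\t{ev.relation_type}\t{ev.classifier}\n"
        )
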