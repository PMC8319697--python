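"""Synthetic PubTator corpora with planted entities and relations.

The generator emulates the *shape* of a literature-mining corpus — short
abstracts split into sentences, typed entity mentions from per-type
dictionaries, and relation trigger keywords between co-mentioned entity
pairs — so every pipeline stage can be exercised offline with a known gold
standard. It makes no attempt at realistic biomedical language: sentences
are templated, entity names are pronounceable consonant-vowel strings, and
each relation sentence carries exactly one trigger keyword so classifier
failures indicate bugs rather than ambiguity.

Noise dials: ``distractor_sentence_rate`` (sentences with at most one
entity), ``keyword_omission_rate`` (the trigger is replaced by a neutral
verb, leaving fallback-type evidence) and ``surface_variant_rate``
(hyphen/space orthography swaps). All randomness flows from one seeded
Mersenne-Twister generator, so a fixed seed reproduces outputs byte for
byte.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field, asdict

from .corpus_io import Document, EntityMention, split_sentences, write_pubtator
from .lexicon import Lexicon, LexEntry
from .relations import RuleBook, default_rulebook, stem

_CONSONANTS = "bdfgklmnprstvz"
_VOWELS = "aeiou"

#: Words used by the sentence templates; generated entity names must not
#: collide with these (nor with any rulebook keyword) after stemming.
_TEMPLATE_WORDS = (
    "synthetic corpus record in this cohort was frequently observed the "
    "patients were monitored for twelve weeks accompanies study"
).split()

_NEUTRAL_VERB = "accompanies"


class SynthConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedRelation:
    type_a: str
    type_b: str
    relation_type: str
    n_supporting_sentences: int


@dataclass
class SynthConfig:
    n_documents: int = 50
    sentences_per_doc: tuple[int, int] = (3, 8)
    lexicon_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "Disease": 30, "Symptom": 20, "Chemical": 30, "Drug": 30,
            "CPM": 30, "Herb": 30, "Ingredient": 20, "Gene": 20, "Pathway": 10,
        }
    )
    planted_relations: list[PlantedRelation] = field(
        default_factory=lambda: [
            PlantedRelation("Drug", "Disease", "treatment", 4),
            PlantedRelation("Drug", "Disease", "cause", 3),
            PlantedRelation("CPM", "Herb", "entity_origin", 4),
            PlantedRelation("Herb", "Chemical", "int", 3),
            PlantedRelation("Gene", "Disease", "positive_association", 4),
            PlantedRelation("CPM", "Symptom", "treatment", 3),
        ]
    )
    distractor_sentence_rate: float = 0.3
    keyword_omission_rate: float = 0.0
    surface_variant_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "distractor_sentence_rate",
            "keyword_omission_rate",
            "surface_variant_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SynthConfigError(f"{name} must lie in [0, 1], got {v}")


def _forbidden_stems(rulebook: RuleBook) -> frozenset[str]:
    stems = {stem(w) for w in _TEMPLATE_WORDS}
    for rules in rulebook.groups.values():
        for rule in rules:
            for phrase in rule.keyword_stems:
                stems.update(phrase)
    return frozenset(stems)


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def generate_lexicons(
    config: SynthConfig, rulebook: RuleBook | None = None
) -> dict[str, Lexicon]:
    """Per-type lexicons of unique pronounceable names.

    CPM and Herb entries get hyphenated multi-token names (CPMs with a
    "-Tang" formula suffix) to exercise surface normalization. Every token
    of every name is globally unique (except the shared "Tang" suffix), so
    no entry can match inside another entry's mention.
    """
    rulebook = rulebook or default_rulebook()
    rng = random.Random(config.seed)
    forbidden = _forbidden_stems(rulebook)
    used_tokens: set[str] = {"tang", "decoction"}

    def new_token(n_syll: int) -> str:
        while True:
            tok = "".join(_syllable(rng) for _ in range(n_syll))
            if tok not in used_tokens and stem(tok) not in forbidden:
                used_tokens.add(tok)
                return tok

    lexicons: dict[str, Lexicon] = {}
    for etype in sorted(config.lexicon_sizes):
        size = config.lexicon_sizes[etype]
        lex = Lexicon(entity_type=etype)
        for i in range(size):
            cid = f"{etype.upper()}:{i:04d}"
            if etype in ("CPM", "Herb"):
                parts = [new_token(2).capitalize() for _ in range(rng.randint(2, 3))]
                if etype == "CPM":
                    parts.append("Tang")
                name = "-".join(parts)
            else:
                name = new_token(rng.randint(2, 3)).capitalize()
            lex.entries[cid] = LexEntry(cid, name, etype, frozenset({name}))
        lexicons[etype] = lex.compile()
    return lexicons


def write_lexicon_tsv(lex: Lexicon, path: str, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(f"# synthetic lexicon  entity_type={lex.entity_type}  seed={seed}\n")
        for cid in sorted(lex.entries):
            e = lex.entries[cid]
            syns = sorted(e.surfaces - {e.preferred_name})
            fh.write(f"{cid}\t{e.preferred_name}" + ("\t" + "|".join(syns) if syns else "") + "\n")


def _variant(surface: str) -> str:
    if "-" in surface:
        return surface.replace("-", " ")
    if " " in surface:
        return surface.replace(" ", "-")
    return surface


def generate_corpus(
    config: SynthConfig,
    lexicons: dict[str, Lexicon],
    rulebook: RuleBook | None = None,
) -> tuple[list[Document], list[EntityMention], list[tuple[str, str, str, str]]]:
    """Generate (documents, gold mentions, gold relations).

    Documents come back sentence-split and *without* mentions (the corpus a
    tagger sees); gold mentions list every planted entity occurrence; gold
    relations are (id_a, id_b, family_name, relation_type) rows, one per
    planted pair. Each planted relation is realized as
    ``n_supporting_sentences`` sentences "<A> <keyword> <B>." with the
    keyword drawn from the rulebook set of the planted type.
    """
    rulebook = rulebook or default_rulebook()
    rng = random.Random(config.seed + 1)

    # Choose a distinct entity pair per planted relation.
    used_pairs: set[frozenset] = set()
    gold_relations: list[tuple[str, str, str, str]] = []
    relation_sentences: list[tuple] = []  # (text, [(surface, etype, cid, offset)])
    for planted in config.planted_relations:
        family = rulebook.family_of(planted.type_a, planted.type_b)
        if family is None:
            raise SynthConfigError(
                f"no pair family allows ({planted.type_a}, {planted.type_b})"
            )
        keywords = [
            r.keywords
            for r in rulebook.rules_for(family)
            if r.relation_type == planted.relation_type
        ]
        if planted.relation_type == rulebook.fallback_for(family):
            keywords = [()]
        if not keywords:
            raise SynthConfigError(
                f"relation type {planted.relation_type!r} not defined for "
                f"family {rulebook.family_name(family)}"
            )
        if keywords[0] == () and planted.relation_type != rulebook.fallback_for(family):
            raise SynthConfigError(
                f"relation type {planted.relation_type!r} has no keywords"
            )
        for _ in range(1000):
            cid_a = rng.choice(sorted(lexicons[family[0]].entries))
            cid_b = rng.choice(sorted(lexicons[family[1]].entries))
            if cid_a != cid_b and frozenset((cid_a, cid_b)) not in used_pairs:
                used_pairs.add(frozenset((cid_a, cid_b)))
                break
        else:  # pragma: no cover - tiny lexicons only
            raise SynthConfigError("could not find an unused entity pair")
        gold_relations.append(
            (cid_a, cid_b, rulebook.family_name(family), planted.relation_type)
        )
        for _ in range(planted.n_supporting_sentences):
            surf_a = lexicons[family[0]].entries[cid_a].preferred_name
            surf_b = lexicons[family[1]].entries[cid_b].preferred_name
            if rng.random() < config.surface_variant_rate:
                surf_a = _variant(surf_a)
            if rng.random() < config.surface_variant_rate:
                surf_b = _variant(surf_b)
            if keywords[0] and rng.random() >= config.keyword_omission_rate:
                kw = rng.choice(keywords[0])
            else:
                kw = _NEUTRAL_VERB
            text = f"{surf_a} {kw} {surf_b}."
            relation_sentences.append(
                (
                    text,
                    [
                        (surf_a, family[0], cid_a, 0),
                        (surf_b, family[1], cid_b, len(surf_a) + len(kw) + 2),
                    ],
                )
            )
    rng.shuffle(relation_sentences)

    def distractor() -> tuple:
        if rng.random() < 0.5:
            return ("The patients were monitored for twelve weeks.", [])
        etype = rng.choice(sorted(t for t, l in lexicons.items() if l.entries))
        cid = rng.choice(sorted(lexicons[etype].entries))
        surf = lexicons[etype].entries[cid].preferred_name
        return (f"In this cohort {surf} was frequently observed.", [(surf, etype, cid, 15)])

    # Assemble documents; every relation sentence must be placed.
    pool = list(relation_sentences)
    doc_sentences: list[list[tuple]] = []
    lo, hi = config.sentences_per_doc
    for _ in range(config.n_documents):
        k = rng.randint(lo, hi)
        sents = []
        for _ in range(k):
            if pool and rng.random() >= config.distractor_sentence_rate:
                sents.append(pool.pop())
            else:
                sents.append(distractor())
        doc_sentences.append(sents)
    for i, sent in enumerate(pool):  # leftovers, round-robin
        doc_sentences[i % max(len(doc_sentences), 1)].append(sent)

    docs: list[Document] = []
    gold_mentions: list[EntityMention] = []
    for idx, sents in enumerate(doc_sentences):
        pmid = str(9000000 + idx)
        title = f"Synthetic corpus record {pmid}."
        abstract = " ".join(text for text, _ in sents)
        doc = split_sentences(Document(pmid=pmid, title=title, abstract=abstract))
        offset = len(title) + 1
        for text, ments in sents:
            for surf, etype, cid, rel_off in ments:
                start = offset + rel_off
                gold_mentions.append(
                    EntityMention(pmid, start, start + len(surf), surf, etype, cid)
                )
            offset += len(text) + 1
        docs.append(doc)
    return docs, gold_mentions, gold_relations


def corrupt_for_eval(
    gold_mentions: list[EntityMention],
    fp_rate: float,
    fn_rate: float,
    seed: int,
) -> list[EntityMention]:
    """Predictions with known expected quality: each gold mention is dropped
    with probability ``fn_rate`` and, independently, a spurious mention is
    injected with probability ``fp_rate`` per gold mention, so expected
    recall is ``1 - fn_rate``."""
    rng = random.Random(seed)
    predicted: list[EntityMention] = []
    for i, m in enumerate(gold_mentions):
        if rng.random() >= fn_rate:
            predicted.append(m)
        if rng.random() < fp_rate:
            base = 1_000_000 + 10 * i
            predicted.append(
                EntityMention(
                    m.doc_pmid, base, base + 6, "spurio", m.entity_type,
                    f"FP:{i:06d}", "dictionary",
                )
            )
    return predicted


def write_outputs(
    config: SynthConfig,
    outdir: str,
    rulebook: RuleBook | None = None,
) -> dict[str, str]:
    """Generate and write the full fixture set to ``outdir``.

    Files: per-type lexicon TSVs, ``corpus.pubtator`` (no annotations),
    ``gold_mentions.pubtator`` (with annotations), ``gold_relations.tsv``
    and ``config.json`` echoing the configuration and seed.
    """
    os.makedirs(outdir, exist_ok=True)
    lexicons = generate_lexicons(config, rulebook)
    docs, gold_mentions, gold_relations = generate_corpus(config, lexicons, rulebook)
    paths = {}
    for etype, lex in sorted(lexicons.items()):
        p = os.path.join(outdir, f"lexicon_{etype.lower()}.tsv")
        write_lexicon_tsv(lex, p, seed=config.seed)
        paths[f"lexicon_{etype}"] = p

    paths["corpus"] = os.path.join(outdir, "corpus.pubtator")
    with open(paths["corpus"], "w", encoding="utf-8") as fh:
        write_pubtator(docs, fh)

    by_pmid: dict[str, list[EntityMention]] = {}
    for m in gold_mentions:
        by_pmid.setdefault(m.doc_pmid, []).append(m)
    gold_docs = []
    for d in docs:
        gd = Document(d.pmid, d.title, d.abstract, sentences=list(d.sentences))
        gd.mentions = sorted(
            by_pmid.get(d.pmid, []), key=lambda m: (m.start, m.end, m.entity_type)
        )
        gold_docs.append(gd)
    paths["gold_mentions"] = os.path.join(outdir, "gold_mentions.pubtator")
    with open(paths["gold_mentions"], "w", encoding="utf-8") as fh:
        write_pubtator(gold_docs, fh)

    paths["gold_relations"] = os.path.join(outdir, "gold_relations.tsv")
    with open(paths["gold_relations"], "w", encoding="utf-8") as fh:
        fh.write(f"# seed={config.seed}\n")
        fh.write("id_a\tid_b\tfamily\trelation_type\n")
        for row in gold_relations:
            fh.write("\t".join(row) + "\n")

    paths["config"] = os.path.join(outdir, "config.json")
    cfg = asdict(config)
    cfg["planted_relations"] = [asdict(p) for p in config.planted_relations]
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
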