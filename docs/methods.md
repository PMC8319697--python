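# Methods

## Problem setting

Literature-scale knowledge about a disease is spread over tens of thousands
of abstracts. This package implements the standard lightweight mining stack
for that setting — dictionary NER, sentence-level co-occurrence, keyword-rule
relation typing, confidence pooling, graph export — for a nine-type entity
vocabulary spanning biomedical (Disease, Symptom, Chemical, Drug, Gene,
Pathway) and TCM (CPM, Herb, Ingredient) entities. Heavyweight components
(trained NER taggers, fine-tuned sentence classifiers) are deliberately
*interfaces*: their outputs are ingested as PubTator pre-annotations or
through the relation-classifier plugin hook, so the pipeline is reproducible
without model downloads.

## Corpus model and offsets

A document is `title + " " + abstract`; all character offsets are 0-based,
half-open, into that concatenation (the PubTator convention). Sentence spans
are computed by a shipped rule-based splitter: a run of `.!?` followed by
whitespace ends a sentence unless the preceding word is on a short
abbreviation guard list (`e.g.`, `i.e.`, `et`, `al.`, `fig.`, ...). The
splitter is pluggable; the default is deterministic so results reproduce
exactly. Titles without terminal punctuation merge with the first abstract
sentence — acceptable for mining, where only co-sentence structure matters.
Mentions that cross a computed sentence boundary are kept in a per-document
diagnostic list but excluded from relation extraction, since the extraction
model is strictly sentence-based and no principled assignment exists for a
span touching two sentences.

## Dictionary matching

Surfaces are normalized by case-folding, mapping hyphens/underscores to
spaces, and collapsing whitespace; matching operates on the resulting *token
sequences*, so hits cannot start or end inside a word and `Huang-Lian`,
`huang lian` and `HUANG LIAN` are one key. Tagging is greedy
longest-match-then-leftmost within each entity type; overlapping mentions of
*different* types (e.g. glucose as both Chemical and Ingredient) are all
emitted, because the downstream pair schema is what decides which typed view
participates in which relation. Matching uses a hash index over token tuples
with a maximum-length bound — with desk-scale dictionaries this is as fast as
an automaton and much simpler.

Variant expansion adds hyphen/space alternations and the `tang`/`decoction`
formula-suffix alternation. Transliteration equivalence across romanization
systems (e.g. Korean vs pinyin renderings of one formula) is *not* attempted:
it is a known recall limitation with no defensible closed rule set, and is
documented rather than guessed at.

The frequency filter keeps an entity iff its corpus-wide mention count is at
least `min_entity_count` (default 3); rarer entities' mentions are routed, in
full, to a serialized review list for manual triage, with a whitelist file to
reinstate confirmed ones. The threshold applies to entities regardless of
which tagger produced the mentions.

## Pair schema and rulebook

The default schema allows 31 entity-type pair families. Each family maps to
exactly one keyword group:

* **treatment group** (`treatment`, `cause`, fallback `other`) — every
  {CPM, Herb, Drug, Chemical, Ingredient} × {Disease, Symptom} pair, plus
  Symptom–Disease. Ingredient–Disease sits here because ingredient-level
  therapeutic/causal claims are graded against plant–disease references.
* **composition/interaction group** (`entity_origin`, `advise`, `int`,
  `effect`, `mechanism`, `negative`, fallback `other`) — compound–compound
  pairs where one side can contain the other (CPM/Herb × Herb, Ingredient,
  Drug, Chemical); the remaining compound pairs (Ingredient–Drug,
  Ingredient–Chemical, Drug–Chemical) use the same group minus
  `entity_origin`.
* **association group** (`positive_association`, `negative_association`,
  fallback `other`) — every Gene- or Pathway-containing family.

Keyword sets follow the conventional trigger vocabularies of the
plant–disease, drug–drug-interaction and gene–disease (EU-ADR-style) corpora:
e.g. therapy/treating/cure/remedy/inhibit → `treatment`;
induce/cause/side effect/influence/dynamic → `cause`;
avoid/"should not be" → `advise`; interaction/and/between → `int`;
enhance/against/demonstrated → `effect`; metabolize/decrease/increase →
`mechanism`; include/contain → `entity_origin`; effect/induce/target →
`positive_association`; indifference/no → `negative_association`. The
rulebook ships as an editable YAML file; priority among a family's types is
their listed order, which also breaks aggregation ties deterministically.

Keyword matching is stem-based phrase matching anywhere in the sentence. The
stemmer is a small suffix stripper (plural `-s/-es/-ies`, `-ing`, `-ed`, then
final-`e` folding) applied identically to keywords and sentence tokens, so
`cure/cured/cures/curing` share one stem. A full dependency-tree rule engine
was considered and rejected: the published rule sets for such engines are not
reproducible, whereas sentence-window matching is, and the window is exposed
as configuration through the rulebook. The high-noise triggers `and`,
`between`, `no` count only when they occur strictly between the two entity
spans, which removes the bulk of their false positives at no recall cost in
the templated test regime.

Candidates additionally exclude self-pairs (same canonical id) and pairs of
overlapping spans — without the latter, one surface double-tagged under two
types would relate an occurrence to itself.

## Confidence pooling

Sentence-level evidence is grouped per (entity a, entity b, family). With
`n_t` sentences voting for type `t` out of `n` co-occurrence sentences, the
pair's majority type maximizes `n_t` (fallback evidence counts toward `n` but
can only be the majority when no typed evidence exists; ties break by
rulebook priority), `confidence = n_majority / n`, `support = n_majority`.
An edge survives iff `support >= min_support` (default 2) and
`confidence > confidence_threshold` (default 0.5, strict). The defaults are
this package's choice of a conservative operating point — a relation must be
seen at least twice and be the strict majority reading; both knobs are
exposed because no canonical values exist for this family of heuristics.
Edge counts are non-increasing in both knobs by construction.

## Graph schema

Nodes carry id, preferred name, entity type, optional MeSH id (recognized
when the canonical id itself is in the `MESH:` namespace) and mention count.
Edges carry relation type, the matched keyword set, supporting PMIDs,
confidence and support. Parallel edges of different relation types between
one pair are retained (keyed by type); same-type duplicates merge by
pmid/keyword union, keeping the larger confidence. Set-valued attributes are
stored as sorted pipe-joined strings so GraphML round-trips losslessly.
`graph_stats` counts "properties" as non-empty attribute values across all
nodes and edges — stated explicitly because the term has no standard
definition.

## Evaluation conventions

NER scoring is set-based over (pmid, span, type) or (pmid, id, type) keys;
zero denominators report 0. Relation grading first intersects predicted and
reference *pairs* (type-blind — the "overlapped relationships"), then grades
types on the intersection via a predicted × reference confusion matrix;
`correct rate = trace / total`, reported as a two-decimal percentage with
round-half-even, and `n/a` when no pairs overlap. Comparisons against
published two-decimal figures use ±0.01 percentage points, since printed
tables mix rounding and truncation (e.g. 269/275 = 97.818% printed as
97.81). `f1` accepts fractions or percentages and returns the harmonic mean
on the input scale.

## Synthetic generator

The generator emulates the corpus *shape* only: abstracts of 3–8 sentences,
each relation realized as `"<A> <keyword> <B>."` with the keyword drawn from
the planted type's rulebook set, distractor sentences containing at most one
entity, and per-type lexicons of consonant-vowel names (CPM/Herb names
hyphenated, CPMs with a `-Tang` suffix, to exercise normalization). Entity
name tokens are globally unique and rejection-sampled away from every
rulebook keyword stem and template word, so in the zero-noise regime the
planted gold is exactly recoverable and any miss is a pipeline bug. It does
not model realistic language: no anaphora, no multi-relation sentences
(except the deliberately unambiguous one-keyword templates), no topic
structure — so perfect synthetic scores bound implementation correctness,
not real-corpus accuracy.

Noise dials: `keyword_omission_rate` swaps the trigger for a neutral verb
(producing fallback-type evidence), `surface_variant_rate` swaps
hyphen/space orthography, `distractor_sentence_rate` sets the fraction of
filler sentences (default 0.25–0.3, roughly the share of sentences in
abstract corpora that carry no typed pair). `corrupt_for_eval` drops gold
mentions with probability `fn_rate` and injects spurious ones at `fp_rate`,
giving predictions with analytically known expected recall `1 - fn_rate`;
replicate seeds should be drawn from one master stream (adjacent integer
seeds give correlated first draws from the underlying Mersenne Twister).

All generation flows from a single seeded `random.Random`; a fixed seed
yields byte-identical files, and the seed is echoed in the config dump and
file headers.

## Problem sizes

The shipped tests and the acceptance script run at desk scale by design:
30–60 documents, lexicons of 4–40 entries per type, 8–10 planted relations
with 3–10 supporting sentences, 50 noise replicates. These sizes give exact
recovery checks and binomial error bounds with comfortable margin while the
whole suite runs in seconds.

## Known limitations

* Dictionary NER cannot find names absent from the lexicons, and
  romanization variance across transliteration systems is out of scope.
* Keyword typing reads the whole sentence window; a trigger that belongs to
  a different clause than the entity pair still counts (except the
  between-only triggers). Dependency-scoped matching would be the upgrade
  path, via the rulebook's `match_mode`.
* The confidence formula treats sentences as independent votes; repeated
  boilerplate (e.g. structured-abstract headings) can inflate support.
* Relation direction is implied by the family (drug→treats→disease), not
  modeled; edges are stored undirected with family-ordered endpoints.
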