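# litkg

Tools for mining a typed biomedical knowledge graph out of PubTator-formatted
abstracts, aimed at corpora that mix "Western" biomedical entities (diseases,
drugs, chemicals, genes, pathways, symptoms) with Traditional Chinese Medicine
vocabularies (Chinese Patent Medicines, herbs, ingredients) — the setting of
stroke literature mining, where treatments are reported in both traditions but
rarely linked in one structured resource.

The pipeline:

1. **Corpus I/O** — read/write PubTator blocks (`pmid|t|`, `pmid|a|`,
   tab-separated mention lines) with validated 0-based character offsets into
   `title + " " + abstract`, plus a deterministic rule-based sentence splitter.
2. **Dictionary NER** — longest-match tagging over normalized token sequences
   against per-type lexicons (TSV: `canonical_id`, `preferred_name`,
   `syn1|syn2|...`), with orthographic variant expansion (hyphen/space,
   tang/decoction) and a corpus frequency filter that routes entities with
   fewer than `min_entity_count` mentions (default 3) to a manual-review list.
   Pre-annotated mentions from upstream taggers are ingested untouched.
3. **Relation extraction** — within-sentence co-occurrence candidates over an
   entity-pair family schema; keyword-rule typing per family group
   (treatment/cause, interaction/advise/effect/mechanism/negative,
   entity-origin, positive/negative gene association) with stemmed phrase
   matching; corpus-level pooling where each pair's *confidence* is the
   majority fraction of its sentence-level evidence,

       confidence(a, b) = max_t n_t(a, b) / n(a, b),

   and an edge survives when `support >= min_support` and
   `confidence > confidence_threshold`. A plugin hook lets a trained sentence
   classifier label the keyword-less sentences; rule matches always win.
4. **Knowledge graph** — nodes (id, name, type, MeSH id, mention count) and
   typed edges (relation type, keywords, PMIDs, confidence, support) as a
   `networkx.MultiGraph`, exported to GraphML, Neo4j bulk-import CSV, or a TSV
   triple dump.
5. **Evaluation** — NER P/R/F1 against gold mentions (strict-span or
   id-level); relation grading on *overlapped* pairs (pairs found by both the
   miner and a reference database) via a predicted-vs-reference confusion
   matrix and the correct rate

       CR = correct classification relationships / overlapped relationships.

6. **Synthetic corpora** — a seeded generator that plants dictionary entities
   and relation keywords into templated abstracts with configurable
   distractor, keyword-omission and surface-variant rates, yielding gold
   standards for every stage.

## Worked example

Generate a synthetic fixture set, tag it, and score it:

```sh
litkg synth --seed 42 --outdir fixtures
litkg ner tag --lexicon-dir fixtures --min-count 1 fixtures/corpus.pubtator tagged.pubtator
litkg eval ner --gold fixtures/gold_mentions.pubtator tagged.pubtator
```

    P=100.00% R=100.00% F1=100.00% (TP=159 FP=0 FN=0)

With zero noise the dictionary tagger recovers every planted mention. Extract
and grade relations:

```sh
litkg relations extract --min-support 1 tagged.pubtator rels.tsv
litkg eval relations --gold fixtures/gold_relations.tsv rels.tsv
```

    overlapped=6 correct=6 correct_rate=100.00%

All six planted edges (e.g. `DRUG:0001 —treatment— DISEASE:0009` with
confidence 1.0 from 4 supporting sentences across PMIDs
`9000000|9000004|9000005`) come back with their planted types; the printed
confusion matrix is diagonal. `litkg build` runs the whole pipeline and writes
the graph (97 nodes, 6 typed edges for this seed).

The same flow works on real PubTator exports: supply your own lexicon TSVs
and, optionally, pre-annotated mentions from upstream NER tools.

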