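"""Co-occurrence candidates, keyword-rule typing, plugin hook, aggregation."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from litkg.relations import (
    PluginContractError,
    RelationEvidence,
    RulebookError,
    aggregate,
    classify_document,
    classify_pair,
    default_rulebook,
    extract_cooccurrence,
    stem,
)

RB = default_rulebook()
from conftest import make_doc


def classify_sentence(rulebook, sentence_ments, doc=None):
    """Build a one-relevant-sentence doc and classify its first candidate."""
    doc = doc or make_doc("1", [sentence_ments])
    (cand,) = extract_cooccurrence(doc, rulebook)
    s, e = doc.sentences[cand.sent_index]
    return classify_pair(cand, doc.full_text[s:e], s, rulebook)


class TestStem:
    @pytest.mark.parametrize(
        "a,b",
        [
            ("treating", "treated"), ("treating", "treats"), ("cure", "cured"),
            ("cures", "curing"), ("induce", "induces"), ("therapy", "therapies"),
            ("demonstrated", "demonstrates"), ("increase", "increasing"),
        ],
    )
    def test_inflections_share_a_stem(self, a, b):
        assert stem(a) == stem(b)

    @pytest.mark.parametrize("a,b", [("no", "not"), ("cause", "cure"), ("and", "an")])
    def test_distinct_words_keep_distinct_stems(self, a, b):
        assert stem(a) != stem(b)


class TestCooccurrence:
    def test_drug_disease_pair(self, rulebook):
        doc = make_doc("1", [[("Aspirin", "Drug", "DB1"), ("stroke", "Disease", "M:1")]])
        (cand,) = extract_cooccurrence(doc, rulebook)
        assert cand.family == ("Drug", "Disease")
        assert cand.mention_a.entity_type == "Drug"  # oriented per family

    def test_cross_product_counts(self, rulebook):
        doc = make_doc(
            "1",
            [[
                ("Aspirin", "Drug", "DB1"), ("Warfarin", "Drug", "DB2"),
                ("stroke", "Disease", "M:1"), ("TIA", "Disease", "M:2"),
            ]],
        )
        cands = extract_cooccurrence(doc, rulebook)
        # 2x2 Drug-Disease cross product; Drug-Drug and Disease-Disease are
        # not allowed families
        assert len(cands) == 4
        assert all(c.family == ("Drug", "Disease") for c in cands)

    def test_mentions_in_different_sentences_never_pair(self, rulebook):
        doc = make_doc(
            "1", [[("Aspirin", "Drug", "DB1")], [("stroke", "Disease", "M:1")]]
        )
        assert extract_cooccurrence(doc, rulebook) == []

    def test_self_pair_excluded(self, rulebook):
        doc = make_doc("1", [[("stroke", "Disease", "M:1"), ("CVA", "Disease", "M:1")]])
        assert extract_cooccurrence(doc, rulebook) == []

    def test_oracle_equivalence_on_random_documents(self, rulebook):
        """Candidates equal brute-force pair enumeration filtered by schema."""
        rng = random.Random(20240917)
        types = ["Drug", "Disease", "Gene", "Herb", "CPM", "Chemical", "Symptom"]
        for trial in range(100):
            sentences = []
            for _ in range(rng.randint(1, 4)):
                ments = [
                    (f"ent{rng.randrange(40)}x", rng.choice(types), None)
                    for _ in range(rng.randint(0, 4))
                ]
                ments = [
                    (s, t, f"{t.upper()}:{s}") for s, t, _ in ments
                ]
                sentences.append(ments)
            doc = make_doc(str(trial), sentences)
            got = {
                (c.sent_index, frozenset((c.mention_a.norm_id, c.mention_b.norm_id)),
                 c.family)
                for c in extract_cooccurrence(doc, rulebook)
            }
            expected = set()
            for m1 in doc.mentions:
                for m2 in doc.mentions:
                    if m1 is m2 or m1.norm_id == m2.norm_id:
                        continue
                    s1 = doc.sentence_index_of(m1)
                    if s1 != doc.sentence_index_of(m2):
                        continue
                    if m1.start < m2.end and m2.start < m1.end:
                        continue
                    fam = rulebook.family_of(m1.entity_type, m2.entity_type)
                    if fam is not None:
                        expected.add(
                            (s1, frozenset((m1.norm_id, m2.norm_id)), fam)
                        )
            assert got == expected


class TestClassifyPair:
    def test_treatment_keyword(self, rulebook):
        ev = classify_sentence(
            rulebook,
            [("Aspirin", "Drug", "DB1"), ("stroke", "Disease", "M:1")],
            make_doc_with_middle("Aspirin", "Drug", "DB1", "useful for treating",
                                 "stroke", "Disease", "M:1"),
        )
        assert (ev.relation_type, ev.matched_keyword) == ("treatment", "treating")

    def test_cause_keyword(self, rulebook):
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("Warfarin", "Drug", "DB2", "may induce",
                                 "bleeding", "Disease", "M:2"),
        )
        assert ev.relation_type == "cause"
        assert ev.matched_keyword == "induce"

    def test_stemmed_match(self, rulebook):
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("Aspirin", "Drug", "DB1", "cures",
                                 "stroke", "Disease", "M:1"),
        )
        assert (ev.relation_type, ev.matched_keyword) == ("treatment", "cure")

    def test_phrase_keyword(self, rulebook):
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("Aspirin", "Drug", "DB1", "has the side effect of",
                                 "ulcers", "Disease", "M:3"),
        )
        assert (ev.relation_type, ev.matched_keyword) == ("cause", "side effect")

    def test_no_keyword_falls_back(self, rulebook):
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("BRCA1", "Gene", "G:1", "was measured alongside",
                                 "stroke", "Disease", "M:1"),
        )
        assert ev.relation_type == "other"
        assert ev.matched_keyword is None

    def test_priority_order_breaks_keyword_ties(self, rulebook):
        # both a treatment and a cause trigger present: treatment is listed
        # first in the rulebook and wins
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("Aspirin", "Drug", "DB1",
                                 "treating one disease may cause",
                                 "bleeding", "Disease", "M:2"),
        )
        assert ev.relation_type == "treatment"

    def test_between_only_trigger_inside_gap(self, rulebook):
        ev = classify_sentence(
            rulebook, None,
            make_doc_with_middle("Danshen", "Herb", "H:1", "and",
                                 "Aspirin", "Drug", "DB1"),
        )
        assert (ev.relation_type, ev.matched_keyword) == ("int", "and")

    def test_between_only_trigger_outside_gap_ignored(self, rulebook):
        doc = make_doc_with_middle(
            "Danshen", "Herb", "H:1", "combined with",
            "Aspirin", "Drug", "DB1", suffix=" and placebo",
        )
        ev = classify_sentence(rulebook, None, doc)
        assert ev.matched_keyword != "and"
        assert ev.relation_type == "other"

    def test_unknown_family_is_configuration_error(self, rulebook):
        doc = make_doc("1", [[("a", "Drug", "D:1"), ("b", "Disease", "M:1")]])
        (cand,) = extract_cooccurrence(doc, rulebook)
        bad = cand.__class__(cand.pmid, cand.sent_index, cand.mention_a,
                             cand.mention_b, ("Drug", "Drug"))
        with pytest.raises(RulebookError):
            classify_pair(bad, doc.full_text, 0, rulebook)


class TestPlugin:
    def _doc_no_keyword(self):
        return make_doc_with_middle(
            "BRCA1", "Gene", "G:1", "was profiled near", "stroke", "Disease", "M:1"
        )

    def test_fallback_echo_plugin_matches_rule_only_run(self, rulebook):
        doc = self._doc_no_keyword()
        rule_only = classify_document(doc, rulebook)
        with_plugin = classify_document(
            doc, rulebook, plugin=lambda s, c: rulebook.fallback_for(c.family)
        )
        assert [e.relation_type for e in rule_only] == [
            e.relation_type for e in with_plugin
        ]

    def test_rule_precedence_over_plugin(self, rulebook):
        doc = make_doc_with_middle(
            "Aspirin", "Drug", "DB1", "can cure", "stroke", "Disease", "M:1"
        )
        (ev,) = classify_document(doc, rulebook, plugin=lambda s, c: "cause")
        assert ev.relation_type == "treatment"
        assert ev.classifier == "rule"

    def test_plugin_labels_keywordless_sentence(self, rulebook):
        (ev,) = classify_document(
            self._doc_no_keyword(), rulebook,
            plugin=lambda s, c: "positive_association",
        )
        assert (ev.relation_type, ev.classifier) == ("positive_association", "plugin")

    def test_plugin_contract_violation(self, rulebook):
        with pytest.raises(PluginContractError):
            classify_document(
                self._doc_no_keyword(), rulebook, plugin=lambda s, c: "treatment"
            )


def make_doc_with_middle(surf_a, type_a, id_a, middle, surf_b, type_b, id_b,
                         suffix=""):
    """One-sentence doc '<A> <middle> <B><suffix>.' with two mentions."""
    from litkg.corpus_io import Document, EntityMention

    title = "T."
    text = f"{surf_a} {middle} {surf_b}{suffix}."
    doc = Document("1", title, text)
    off = len(title) + 1
    a_start = off
    b_start = off + len(surf_a) + len(middle) + 2
    doc.sentences = [(0, len(title)), (off, off + len(text))]
    doc.mentions = [
        EntityMention("1", a_start, a_start + len(surf_a), surf_a, type_a, id_a),
        EntityMention("1", b_start, b_start + len(surf_b), surf_b, type_b, id_b),
    ]
    doc.validate()
    return doc


def _evidence(id_a, id_b, rtype, pmid="1", family=("Drug", "Disease")):
    from litkg.corpus_io import EntityMention

    a = EntityMention(pmid, 0, 1, "a", family[0], id_a)
    b = EntityMention(pmid, 2, 3, "b", family[1], id_b)
    kw = None if rtype == "other" else rtype
    return RelationEvidence(pmid, 0, a, b, family, rtype, kw)


class TestAggregate:
    def test_unanimous_evidence(self, rulebook):
        evs = [_evidence("D:1", "M:1", "treatment") for _ in range(3)]
        kept, dropped = aggregate(evs, rulebook, min_support=2, confidence_threshold=0.5)
        (rel,) = kept
        assert (rel.majority_type, rel.confidence, rel.support, rel.n) == (
            "treatment", 1.0, 3, 3,
        )

    def test_split_evidence_at_strict_threshold_dropped(self, rulebook):
        evs = [_evidence("D:1", "M:1", "treatment"), _evidence("D:1", "M:1", "cause")]
        kept, dropped = aggregate(evs, rulebook, min_support=1, confidence_threshold=0.5)
        assert kept == []
        assert dropped[0].confidence == 0.5

    def test_single_evidence_below_min_support_dropped(self, rulebook):
        kept, dropped = aggregate(
            [_evidence("D:1", "M:1", "treatment")], rulebook,
            min_support=2, confidence_threshold=0.5,
        )
        assert kept == [] and len(dropped) == 1

    def test_fallback_counts_toward_n_but_not_majority(self, rulebook):
        evs = [
            _evidence("D:1", "M:1", "treatment"),
            _evidence("D:1", "M:1", "other"),
            _evidence("D:1", "M:1", "other"),
        ]
        kept, dropped = aggregate(evs, rulebook, min_support=1, confidence_threshold=0.0)
        (rel,) = kept
        assert rel.majority_type == "treatment"
        assert rel.n == 3 and rel.support == 1
        assert rel.confidence == pytest.approx(1 / 3)

    def test_all_fallback_majority_is_fallback(self, rulebook):
        evs = [_evidence("D:1", "M:1", "other")] * 3
        kept, _ = aggregate(evs, rulebook, min_support=1, confidence_threshold=0.5)
        assert kept[0].majority_type == "other"

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.integers(0, 3),  # pair id
                st.sampled_from(["treatment", "cause", "other"]),
            ),
            min_size=1, max_size=30,
        )
    )
    def test_conservation_and_threshold_monotonicity(self, rows):
        rulebook = RB
        evs = [_evidence(f"D:{p}", f"M:{p}", t) for p, t in rows]
        kept, dropped = aggregate(evs, rulebook, min_support=1, confidence_threshold=0.0)
        for rel in kept + dropped:
            assert sum(rel.type_counts.values()) == rel.n
            assert rel.confidence == pytest.approx(rel.support / rel.n)
        sizes_conf = [
            len(aggregate(evs, rulebook, 1, thr)[0]) for thr in (0.0, 0.3, 0.5, 0.8, 1.0)
        ]
        assert sizes_conf == sorted(sizes_conf, reverse=True)
        sizes_sup = [
            len(aggregate(evs, rulebook, ms, 0.0)[0]) for ms in (1, 2, 3, 5)
        ]
        assert sizes_sup == sorted(sizes_sup, reverse=True)
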