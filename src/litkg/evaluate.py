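"""Evaluation arithmetic for text-mined entities and relations.

Three instruments:

* NER precision/recall/F1 against gold mention sets, either strict-span
  (pmid, span, type) or id-level (pmid, canonical id, type);
* a predicted-vs-reference confusion matrix over the *overlapped* entity
  pairs — pairs found by both the miner and a reference database,
  regardless of predicted type;
* the correct rate: correctly classified relationships divided by
  overlapped relationships, i.e. the trace over the grand total of that
  matrix.

Percentages are reported to two decimals (round-half-even); a zero
denominator yields 0 for the NER metrics and a not-applicable ``None`` for
the correct rate.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import IO, Iterable

from .corpus_io import EntityMention
from .relations import AggregatedRelation

_MATCH_MODES = ("strict_span", "id_only")


@dataclass(frozen=True)
class EvalReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    match_mode: str

    @property
    def precision(self) -> float:
        d = self.true_positives + self.false_positives
        return self.true_positives / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.true_positives + self.false_negatives
        return self.true_positives / d if d else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


def _mention_key(m: EntityMention, mode: str):
    if mode == "strict_span":
        return (m.doc_pmid, m.start, m.end, m.entity_type)
    return (m.doc_pmid, m.norm_id, m.entity_type)


def score_ner(
    predicted: Iterable[EntityMention],
    gold: Iterable[EntityMention],
    match_mode: str = "strict_span",
) -> EvalReport:
    """Set-based P/R/F1 of predicted vs gold mentions.

    Duplicate keys collapse (set semantics), so TP+FN equals the number of
    *unique* gold keys and TP+FP the number of unique predicted keys.
    """
    if match_mode not in _MATCH_MODES:
        raise ValueError(f"unknown match mode {match_mode!r}; use {_MATCH_MODES}")
    pset = {_mention_key(m, match_mode) for m in predicted}
    gset = {_mention_key(m, match_mode) for m in gold}
    return EvalReport(
        true_positives=len(pset & gset),
        false_positives=len(pset - gset),
        false_negatives=len(gset - pset),
        match_mode=match_mode,
    )


@dataclass
class ConfusionMatrix:
    """Relation-type confusion over overlapped entity pairs.

    ``counts[(predicted, reference)]`` tallies pairs; rows are predicted
    labels, columns reference labels.
    """

    labels: tuple[str, ...]
    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative cell count")
        for p, r in self.counts:
            if p not in self.labels or r not in self.labels:
                raise ValueError(f"cell ({p!r}, {r!r}) outside label set")

    def cell(self, predicted: str, reference: str) -> int:
        return self.counts.get((predicted, reference), 0)

    @property
    def overlapped_relationships(self) -> int:
        return sum(self.counts.values())

    @property
    def correct_classification_relationships(self) -> int:
        return sum(self.cell(l, l) for l in self.labels)

    def write_csv(self, stream: IO[str]) -> None:
        w = csv.writer(stream)
        w.writerow(["predicted\\reference", *self.labels])
        for p in self.labels:
            w.writerow([p, *(self.cell(p, r) for r in self.labels)])


def correct_rate(matrix: ConfusionMatrix) -> float | None:
    """Trace over grand total, as a fraction; None when no pairs overlap."""
    total = matrix.overlapped_relationships
    if total == 0:
        return None
    return matrix.correct_classification_relationships / total


def correct_rate_from_counts(correct: int, overlapped: int) -> float | None:
    """Correct rate straight from the two named tallies."""
    if overlapped == 0:
        return None
    if not 0 <= correct <= overlapped:
        raise ValueError("correct count must be within [0, overlapped]")
    return correct / overlapped


def percent(value: float | None) -> str:
    """Two-decimal percentage string (round-half-even); 'n/a' for None."""
    if value is None:
        return "n/a"
    q = (Decimal(str(value)) * 100).quantize(Decimal("0.01"), ROUND_HALF_EVEN)
    return f"{q}%"


def _pair_key(entity_a: str, entity_b: str, family: str):
    return (family, frozenset((entity_a, entity_b)))


def score_relations(
    predicted: Iterable[AggregatedRelation | tuple],
    reference: Iterable[tuple],
) -> ConfusionMatrix:
    """Confusion matrix of predicted vs reference relation types.

    ``reference`` rows are (id_a, id_b, family_name, relation_type) tuples;
    ``predicted`` accepts the same tuples or AggregatedRelation objects.
    Only pairs present on both sides (the overlapped relationships) enter
    the matrix; pair identity ignores entity order within a family.
    """
    pred: dict = {}
    for item in predicted:
        if isinstance(item, AggregatedRelation):
            key = _pair_key(item.entity_a, item.entity_b, item.family_name)
            pred[key] = item.majority_type
        else:
            a, b, fam, rtype = item
            pred[_pair_key(a, b, fam)] = rtype
    ref: dict = {}
    for a, b, fam, rtype in reference:
        ref[_pair_key(a, b, fam)] = rtype
    counts: dict[tuple[str, str], int] = {}
    labels: set[str] = set()
    for key, ptype in pred.items():
        if key not in ref:
            continue
        rtype = ref[key]
        labels.update((ptype, rtype))
        counts[(ptype, rtype)] = counts.get((ptype, rtype), 0) + 1
    return ConfusionMatrix(labels=tuple(sorted(labels)), counts=counts)


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall.

    Accepts fractions in [0, 1] or percentages in (1, 100]; a percentage on
    either side puts the result on the percentage scale.
    """
    for v in (precision, recall):
        if not 0 <= v <= 100:
            raise ValueError(f"precision/recall value {v} outside [0, 100]")
    as_percent = precision > 1 or recall > 1
    if as_percent:
        precision, recall = precision / 100, recall / 100
    val = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return val * 100 if as_percent else val
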