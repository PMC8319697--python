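import pytest

from litkg.corpus_io import Document, EntityMention
from litkg.relations import default_rulebook


@pytest.fixture(scope="session")
def rulebook():
    return default_rulebook()


def make_doc(pmid, sentence_mentions, filler="later sentence here"):
    """Build a sentence-split Document from per-sentence mention specs.

    ``sentence_mentions`` is a list of sentences; each sentence is a list of
    (surface, entity_type, canonical_id) mentions, joined by " with " so
    spans never touch. An empty list yields a filler sentence.
    """
    sentences = []
    mentions = []
    cursor = 0
    title = f"Doc {pmid}."
    cursor = len(title) + 1
    parts = []
    for ments in sentence_mentions:
        if not ments:
            text = filler.capitalize() + "."
            parts.append(text)
            sentences.append((cursor, cursor + len(text)))
            cursor += len(text) + 1
            continue
        text = ""
        sent_start = cursor
        for k, (surface, etype, cid) in enumerate(ments):
            if k:
                text += " with "
            start = sent_start + len(text)
            text += surface
            mentions.append(
                EntityMention(pmid, start, start + len(surface), surface, etype, cid)
            )
        text += "."
        parts.append(text)
        sentences.append((sent_start, sent_start + len(text)))
        cursor += len(text) + 1
    doc = Document(pmid=pmid, title=title, abstract=" ".join(parts))
    doc.sentences = [(0, len(title))] + sentences
    doc.mentions = mentions
    doc.validate()
    return doc
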