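"""Entity dictionaries for dictionary-based NER.

A lexicon maps surface forms (a preferred name plus synonyms) onto a
canonical identifier of one entity type, the way term lists exported from
drug/TCM databases (DrugBank, TCMID, ETCM, ...) are organised. Matching is
over *normalized token sequences* rather than raw characters, so "Huang-Lian",
"huang lian" and "HUANG LIAN" all resolve to the same entry and no match can
start or end inside a word.

File format (UTF-8 TSV, one file per entity type, ``#`` comment lines
allowed)::

    canonical_id<TAB>preferred_name<TAB>syn1|syn2|...
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

from .corpus_io import canonical_entity_type

_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"[^\W_]+")


class LexiconError(ValueError):
    """Bad lexicon source file."""


class AmbiguousSurfaceError(LexiconError):
    """One normalized surface maps to two canonical ids of the same type."""


def normalize_surface(text: str) -> str:
    """Case-fold, map hyphens/underscores to spaces, collapse whitespace.

    Idempotent; this is the canonical key space for dictionary matching.
    """
    text = text.casefold().replace("-", " ").replace("_", " ")
    return _WS_RE.sub(" ", text).strip()


def surface_key(text: str) -> tuple[str, ...]:
    """Tokenized normalized form — the key used by the compiled matcher."""
    return tuple(_TOKEN_RE.findall(normalize_surface(text)))


def tokenize_with_offsets(text: str) -> list[tuple[str, int, int]]:
    """Word tokens with character offsets; hyphens and underscores split
    tokens so offsets line up with :func:`surface_key` of any slice."""
    return [(m.group(0), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


@dataclass(frozen=True)
class LexEntry:
    canonical_id: str
    preferred_name: str
    entity_type: str
    surfaces: frozenset[str]

    def __post_init__(self) -> None:
        if not self.canonical_id:
            raise LexiconError("empty canonical_id")
        if any(not s for s in self.surfaces):
            raise LexiconError(f"{self.canonical_id}: empty surface form")


@dataclass
class Lexicon:
    """A compiled per-type dictionary: token-sequence key -> canonical id."""

    entity_type: str
    entries: dict[str, LexEntry] = field(default_factory=dict)
    _index: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)
    max_key_len: int = 0

    def compile(self) -> "Lexicon":
        """(Re)build the matcher index; ambiguity is a hard error."""
        index: dict[tuple[str, ...], str] = {}
        owner: dict[tuple[str, ...], str] = {}
        for cid in sorted(self.entries):
            for surf in sorted(self.entries[cid].surfaces):
                key = surface_key(surf)
                if not key:
                    continue
                if key in index and owner[key] != cid:
                    raise AmbiguousSurfaceError(
                        f"{self.entity_type}: surface {surf!r} maps to both "
                        f"{owner[key]} and {cid}"
                    )
                index[key] = cid
                owner[key] = cid
        self._index = index
        self.max_key_len = max((len(k) for k in index), default=0)
        return self

    def lookup(self, surface: str) -> str | None:
        """Canonical id for a surface form, or None."""
        return self._index.get(surface_key(surface))

    def lookup_key(self, key: tuple[str, ...]) -> str | None:
        return self._index.get(key)

    def name_of(self, canonical_id: str) -> str:
        return self.entries[canonical_id].preferred_name


def load_lexicon(
    source: str | IO[str] | Iterable[str], entity_type: str
) -> Lexicon:
    """Load and compile a lexicon TSV for one entity type.

    Duplicate canonical ids and surfaces shared by two entries are load-time
    errors: ambiguity must be resolved in the source file.
    """
    entity_type = canonical_entity_type(entity_type)
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    lex = Lexicon(entity_type=entity_type)
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise LexiconError(f"line {lineno}: expected >=2 tab-separated fields")
        cid, name = fields[0].strip(), fields[1].strip()
        syns = fields[2].split("|") if len(fields) > 2 and fields[2].strip() else []
        if cid in lex.entries:
            raise LexiconError(f"line {lineno}: duplicate canonical_id {cid}")
        surfaces = frozenset(
            {name} | {s.strip() for s in syns if s.strip()}
        )
        lex.entries[cid] = LexEntry(cid, name, entity_type, surfaces)
    return lex.compile()


# Orthographic variant generation. Transliteration equivalence (e.g. the
# Korean vs pinyin romanizations of one formula name) is deliberately NOT
# attempted: no defensible rule set exists, and it is a known recall limit.

_SUFFIX_ALT = {"tang": "decoction", "decoction": "tang"}


def expand_variants(entry: LexEntry) -> LexEntry:
    """Add deterministic orthographic variants to an entry's surface set.

    Two rewrite rules, applied to every surface: hyphen<->space alternation,
    and "tang"/"decoction" final-token alternation (the two conventional
    renderings of a TCM formula suffix). Never removes a surface.
    """
    new = set(entry.surfaces)
    for surf in entry.surfaces:
        if "-" in surf:
            new.add(surf.replace("-", " "))
        elif " " in surf:
            new.add(surf.replace(" ", "-"))
        norm = normalize_surface(surf)
        toks = norm.split(" ")
        if toks and toks[-1] in _SUFFIX_ALT:
            new.add(" ".join(toks[:-1] + [_SUFFIX_ALT[toks[-1]]]))
    return replace(entry, surfaces=frozenset(new))


def expand_lexicon(lex: Lexicon) -> Lexicon:
    """Variant-expand every entry and recompile."""
    out = Lexicon(entity_type=lex.entity_type)
    out.entries = {cid: expand_variants(e) for cid, e in lex.entries.items()}
    return out.compile()
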