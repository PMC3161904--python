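"""ICD10 term dictionary construction.

The matching dictionary maps normalized disease/symptom terms to level-3
ICD10 codes (one letter + two digits, e.g. ``F20``).  Terms from a national
term table are normalized, rule-generated variants are added (truncation at
specifier phrases, commas and parentheses), and every code is rounded to its
level-3 prefix so that all terms act as synonyms of the generic level-3
meaning.  The 22 ICD10 chapters are derived from the standard code ranges.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "CHAPTER_RANGES",
    "TermEntry",
    "TermDictionary",
    "normalize_text",
    "round_to_level3",
    "generate_variants",
    "build_dictionary",
    "chapter_of",
    "is_level3",
]

#: Standard WHO chapter ranges, inclusive on both ends (level-3 codes).
CHAPTER_RANGES: tuple[tuple[str, str, str], ...] = (
    ("I", "A00", "B99"),
    ("II", "C00", "D48"),
    ("III", "D50", "D89"),
    ("IV", "E00", "E90"),
    ("V", "F00", "F99"),
    ("VI", "G00", "G99"),
    ("VII", "H00", "H59"),
    ("VIII", "H60", "H95"),
    ("IX", "I00", "I99"),
    ("X", "J00", "J99"),
    ("XI", "K00", "K93"),
    ("XII", "L00", "L99"),
    ("XIII", "M00", "M99"),
    ("XIV", "N00", "N99"),
    ("XV", "O00", "O99"),
    ("XVI", "P00", "P96"),
    ("XVII", "Q00", "Q99"),
    ("XVIII", "R00", "R99"),
    ("XIX", "S00", "T98"),
    ("XX", "V01", "Y98"),
    ("XXI", "Z00", "Z99"),
    ("XXII", "U00", "U99"),
)

_LEVEL3_RE = re.compile(r"^[A-Z][0-9]{2}$")

# Punctuation stripped from token boundaries during normalization.  Interior
# characters (hyphens inside words, national letters) are left untouched.
_BOUNDARY_PUNCT = ",;:()[]{}<>\"'«»„“”‘’/\\|@#%&*+=~^…_-"
_SENTENCE_MARKS = ".!?"


def normalize_text(raw: str, keep_sentence_marks: bool = False) -> str:
    """Normalize free text for dictionary matching.

    Lowercases, collapses whitespace runs to single spaces and strips
    punctuation at token boundaries.  National letters (æ/ø/å etc.) are
    preserved; no stemming is applied because matching is exact.  With
    ``keep_sentence_marks`` the sentence-final markers ``.!?`` survive so a
    downstream splitter can use them.
    """
    strip_chars = _BOUNDARY_PUNCT
    if not keep_sentence_marks:
        strip_chars += _SENTENCE_MARKS
    tokens = []
    for tok in raw.lower().split():
        tok = tok.strip(strip_chars)
        if tok:
            tokens.append(tok)
    return " ".join(tokens)


def round_to_level3(code: str) -> str:
    """Round an ICD10 code to its level-3 form (letter + two digits).

    Accepts plain WHO codes (``E10.9``) and the Danish SKS dialect with a
    leading ``D`` prefix (``DF201``).  The prefix is stripped only when it is
    followed by a letter, so genuine ``D``-chapter codes (``D64``) survive.

    Raises ``ValueError`` when no letter+digit+digit core can be found.
    """
    cleaned = code.strip().upper().replace(".", "")
    if len(cleaned) >= 2 and cleaned[0] == "D" and cleaned[1].isalpha():
        cleaned = cleaned[1:]
    core = cleaned[:3]
    if not _LEVEL3_RE.match(core):
        raise ValueError(f"malformed ICD10 code {code!r}: no letter+2-digit core")
    return core


def is_level3(code: str) -> bool:
    return bool(_LEVEL3_RE.match(code))


def chapter_of(code: str) -> str:
    """Return the roman-numeral chapter (I–XXII) of a level-3 code."""
    if not _LEVEL3_RE.match(code):
        raise ValueError(f"not a level-3 ICD10 code: {code!r}")
    for roman, lo, hi in CHAPTER_RANGES:
        if lo <= code <= hi:
            return roman
    raise ValueError(f"code {code!r} falls outside every ICD10 chapter range")


def _light_normalize(raw: str) -> str:
    """Lowercase and collapse whitespace but keep punctuation.

    Variant generation needs the commas/parentheses that full normalization
    strips, so it operates on this lighter form.
    """
    return " ".join(raw.lower().split())


def generate_variants(term: str, specifiers: Sequence[str] = ()) -> list[str]:
    """Generate truncated term variants.

    For every specifier phrase occurring inside the term, the part preceding
    the phrase becomes a variant ("anaemia caused by lead" -> "anaemia").
    Commas are treated the same way (prefix before the first comma), and for
    parentheses both the prefix before ``(`` and the term with the
    parenthesized segment removed are emitted.  Variants are fully
    normalized, de-duplicated, non-empty and never equal to the (normalized)
    original term.
    """
    light = _light_normalize(term)
    raw_variants: list[str] = []
    padded = f" {light} "
    for spec in specifiers:
        spec_l = _light_normalize(spec)
        if not spec_l:
            continue
        idx = padded.find(f" {spec_l} ")
        if idx > 0:
            raw_variants.append(padded[:idx])
    if "," in light:
        raw_variants.append(light.split(",", 1)[0])
    if "(" in light:
        raw_variants.append(light.split("(", 1)[0])
        raw_variants.append(re.sub(r"\([^)]*\)", " ", light))
    original = normalize_text(light)
    seen: set[str] = set()
    out: list[str] = []
    for var in raw_variants:
        norm = normalize_text(var)
        if norm and norm != original and norm not in seen:
            seen.add(norm)
            out.append(norm)
    return out


@dataclass(frozen=True)
class TermEntry:
    """One dictionary row: a normalized term mapped to a level-3 code."""

    term: str
    code: str
    origin: str = "original"  # "original" | "variant"
    parent_term: str = ""

    def __post_init__(self) -> None:
        if self.origin == "variant" and not self.parent_term:
            raise ValueError("variant entries need a parent_term")


@dataclass
class TermDictionary:
    """Compiled term dictionary with longest-match lookup support.

    ``lookup`` maps a normalized term string to its code; ``max_tokens``
    bounds the stepping window.  Blacklisted terms stay in the lookup so
    that their matches can be found and counted as disqualified.
    """

    entries: list[TermEntry] = field(default_factory=list)
    blacklist: frozenset[str] = frozenset()
    skipped_codes: int = 0
    collisions: int = 0
    _lookup: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._lookup:
            for entry in self.entries:
                self._lookup.setdefault(entry.term, entry.code)

    @property
    def max_tokens(self) -> int:
        return max((t.count(" ") + 1 for t in self._lookup), default=0)

    def lookup(self, term: str) -> str | None:
        return self._lookup.get(term)

    def is_blacklisted(self, term: str) -> bool:
        return term in self.blacklist

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[TermEntry]:
        return iter(self.entries)

    # --- persistence -----------------------------------------------------

    def to_table(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("term\tcode\torigin\tparent_term\n")
            for e in sorted(self.entries, key=lambda e: (e.term, e.code)):
                fh.write(f"{e.term}\t{e.code}\t{e.origin}\t{e.parent_term}\n")

    @classmethod
    def from_table(cls, path: str | Path, blacklist: Iterable[str] = ()) -> "TermDictionary":
        entries = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("term"):
                raise ValueError(f"{path}: expected header 'term\\tcode\\torigin\\tparent_term'")
            for line in fh:
                if not line.strip():
                    continue
                term, code, origin, parent = (line.rstrip("\n").split("\t") + [""])[:4]
                entries.append(TermEntry(term, code, origin, parent))
        return cls(entries=entries, blacklist=frozenset(normalize_text(b) for b in blacklist))


def build_dictionary(
    term_table: Iterable[tuple[str, str]],
    specifiers: Sequence[str] = (),
    blacklist: Iterable[str] = (),
) -> TermDictionary:
    """Compile a TermDictionary from (code, term) rows.

    Codes are rounded to level 3 (unroundable rows are counted and skipped),
    terms normalized, variants added with ``origin="variant"``.  Duplicate
    (term, code) pairs collapse to one entry, preferring the original over a
    variant.  A term mapping to two different codes keeps its first code and
    counts a collision.  The blacklist is applied at lookup time by the
    miner, never by deleting entries, so disqualifications stay countable.
    """
    skipped = 0
    best: dict[tuple[str, str], TermEntry] = {}
    for code_raw, term_raw in term_table:
        try:
            code = round_to_level3(code_raw)
        except ValueError:
            skipped += 1
            continue
        term = normalize_text(term_raw)
        if not term:
            skipped += 1
            continue
        key = (term, code)
        if key not in best or best[key].origin == "variant":
            best[key] = TermEntry(term, code, "original", "")
        for var in generate_variants(term_raw, specifiers):
            vkey = (var, code)
            if vkey not in best:
                best[vkey] = TermEntry(var, code, "variant", term)

    entries = sorted(best.values(), key=lambda e: (e.term, e.code, e.origin))
    lookup: dict[str, str] = {}
    collisions = 0
    for e in entries:
        if e.term in lookup and lookup[e.term] != e.code:
            collisions += 1
        else:
            lookup.setdefault(e.term, e.code)
    return TermDictionary(
        entries=entries,
        blacklist=frozenset(normalize_text(b) for b in blacklist if normalize_text(b)),
        skipped_codes=skipped,
        collisions=collisions,
        _lookup=lookup,
    )
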