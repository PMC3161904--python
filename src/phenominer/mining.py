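"""Dictionary-based mining of clinical notes.

Notes are split into sentences on the raw text, tokenized with character
offsets, and scanned left-to-right with a stepping algorithm that tries
windows of 10 down to 1 tokens against the dictionary; the longest exact
match wins and scanning resumes after it, so accepted matches never overlap.
Every candidate match is then classified: blacklisted terms are disqualified
first, then matches preceded (within the same sentence) by a negation token
("no", "never", ...) or another-subject token ("mother", "friend", ...) —
the same idea as the NegEx family of rules.  Disqualified candidates are
kept with their status so the disqualification counts can be reported.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .icd10 import TermDictionary, normalize_text

__all__ = [
    "Note",
    "MiningHit",
    "Lexicons",
    "MiningSummary",
    "split_sentences",
    "tokenize",
    "find_matches",
    "classify_match",
    "mine_corpus",
]

ACCEPTED = "accepted"
NEGATED = "negated"
FALSE_SUBJECT = "false_subject"
BLACKLISTED = "blacklisted"
STATUSES = (ACCEPTED, NEGATED, FALSE_SUBJECT, BLACKLISTED)

MAX_WINDOW = 10  # longest dictionary phrase, in tokens, the stepper tries

_SENTENCE_BOUNDARY = re.compile(r"[.!?\n]")
_TOKEN = re.compile(r"\S+")


@dataclass(frozen=True)
class Note:
    patient_id: str
    date: str = ""
    note_type: str = ""
    text: str = ""

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("note without patient_id")


@dataclass(frozen=True)
class MiningHit:
    """One dictionary match in one note.

    ``start``/``end`` are a half-open, 0-based character span into the
    original note text; normalizing the spanned text reproduces
    ``matched_term``.
    """

    patient_id: str
    note_index: int
    sentence_index: int
    start: int
    end: int
    matched_term: str
    code: str
    status: str


@dataclass(frozen=True)
class Lexicons:
    """Token lists driving match disqualification."""

    negations: frozenset[str] = frozenset()
    subjects: frozenset[str] = frozenset()

    @classmethod
    def from_words(cls, negations: Iterable[str], subjects: Iterable[str]) -> "Lexicons":
        return cls(
            negations=frozenset(normalize_text(w) for w in negations if normalize_text(w)),
            subjects=frozenset(normalize_text(w) for w in subjects if normalize_text(w)),
        )


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Split text into sentence spans on ``. ! ?`` and newlines.

    Returns half-open (start, end) spans into the original text, trimmed of
    surrounding whitespace; empty segments are dropped.
    """
    spans = []
    prev = 0
    for m in _SENTENCE_BOUNDARY.finditer(text):
        spans.append((prev, m.start()))
        prev = m.end()
    spans.append((prev, len(text)))
    out = []
    for a, b in spans:
        seg = text[a:b]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        if a + lstrip < b - rstrip:
            out.append((a + lstrip, b - rstrip))
    return out


def tokenize(text: str, start: int = 0, end: int | None = None) -> list[tuple[str, int, int]]:
    """Tokenize ``text[start:end]`` into (normalized_token, start, end).

    Offsets are absolute into ``text``; tokens that normalize to the empty
    string (pure punctuation) are dropped.
    """
    if end is None:
        end = len(text)
    tokens = []
    for m in _TOKEN.finditer(text, start, end):
        norm = normalize_text(m.group())
        if norm:
            tokens.append((norm, m.start(), m.end()))
    return tokens


def find_matches(
    tokens: Sequence[tuple[str, int, int]], dictionary: TermDictionary
) -> list[tuple[int, int, str, str]]:
    """Scan one sentence's tokens for dictionary terms.

    Returns (token_start_index, n_tokens, term, code) tuples.  At each
    position windows of ``MAX_WINDOW`` down to 1 tokens are tried; the
    longest exact match is emitted and the scan resumes after it, so matches
    are non-overlapping.
    """
    norms = [t[0] for t in tokens]
    matches = []
    i = 0
    n = len(norms)
    while i < n:
        hit = None
        for w in range(min(MAX_WINDOW, n - i), 0, -1):
            term = " ".join(norms[i : i + w])
            code = dictionary.lookup(term)
            if code is not None:
                hit = (i, w, term, code)
                break
        if hit is None:
            i += 1
        else:
            matches.append(hit)
            i = hit[0] + hit[1]
    return matches


def classify_match(
    matched_term: str,
    prefix_tokens: Sequence[str],
    lexicons: Lexicons,
    dictionary: TermDictionary,
) -> str:
    """Classify a candidate match; precedence blacklist > negation > subject."""
    if dictionary.is_blacklisted(matched_term):
        return BLACKLISTED
    prefix = set(prefix_tokens)
    if prefix & lexicons.negations:
        return NEGATED
    if prefix & lexicons.subjects:
        return FALSE_SUBJECT
    return ACCEPTED


@dataclass
class MiningSummary:
    status_counts: Counter = field(default_factory=Counter)
    n_notes: int = 0
    n_patients: int = 0
    codes_per_patient: dict[str, int] = field(default_factory=dict)

    @property
    def mean_unique_codes(self) -> float:
        if not self.codes_per_patient:
            return 0.0
        return sum(self.codes_per_patient.values()) / len(self.codes_per_patient)


def mine_corpus(
    notes: Sequence[Note],
    dictionary: TermDictionary,
    lexicons: Lexicons,
    excluded_note_types: Iterable[str] = (),
) -> tuple[list[MiningHit], MiningSummary]:
    """Mine a corpus of notes; returns all hits (every status) plus counts.

    The summary's unique-codes-per-patient statistic counts level-3 codes
    from accepted hits only.  Notes of an excluded type are skipped whole.
    Deterministic given its inputs.
    """
    excluded = {t.lower() for t in excluded_note_types}
    hits: list[MiningHit] = []
    summary = MiningSummary()
    accepted_codes: dict[str, set[str]] = {}
    patients: set[str] = set()
    for note_index, note in enumerate(notes):
        patients.add(note.patient_id)
        if note.note_type.lower() in excluded:
            continue
        summary.n_notes += 1
        for sent_index, (s_start, s_end) in enumerate(split_sentences(note.text)):
            tokens = tokenize(note.text, s_start, s_end)
            for tok_i, width, term, code in find_matches(tokens, dictionary):
                status = classify_match(term, [t[0] for t in tokens[:tok_i]], lexicons, dictionary)
                hits.append(
                    MiningHit(
                        patient_id=note.patient_id,
                        note_index=note_index,
                        sentence_index=sent_index,
                        start=tokens[tok_i][1],
                        end=tokens[tok_i + width - 1][2],
                        matched_term=term,
                        code=code,
                        status=status,
                    )
                )
                summary.status_counts[status] += 1
                if status == ACCEPTED:
                    accepted_codes.setdefault(note.patient_id, set()).add(code)
    summary.n_patients = len(patients)
    summary.codes_per_patient = {p: len(c) for p, c in accepted_codes.items()}
    return hits, summary
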