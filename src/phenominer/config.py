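"""Default word lists and config loading.

The negation/subject/specifier/blacklist word lists the pipeline needs are
editable one-phrase-per-line UTF-8 files; small English+Danish defaults
ship as package data.  The stratification exclusion list defaults to the
three classic trivial/symptom codes: pain (R52), cough (R05), itching (L29).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .mining import Lexicons

__all__ = [
    "read_wordlist",
    "default_negations",
    "default_subjects",
    "default_specifiers",
    "default_blacklist",
    "default_excluded_codes",
    "default_lexicons",
]


def read_wordlist(path: str | Path) -> list[str]:
    """One phrase per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def _packaged(name: str) -> list[str]:
    text = resources.files("phenominer.data").joinpath(name).read_text(encoding="utf-8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def default_negations() -> list[str]:
    return _packaged("negations.txt")


def default_subjects() -> list[str]:
    return _packaged("subjects.txt")


def default_specifiers() -> list[str]:
    return _packaged("specifiers.txt")


def default_blacklist() -> list[str]:
    return _packaged("blacklist.txt")


def default_excluded_codes() -> list[str]:
    return _packaged("excluded_codes.txt")


def default_lexicons() -> Lexicons:
    return Lexicons.from_words(default_negations(), default_subjects())
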