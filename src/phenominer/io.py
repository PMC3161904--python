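"""Readers and writers for the pipeline's plain-file formats."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .mining import MiningHit, Note

__all__ = [
    "read_notes",
    "read_assigned",
    "write_hits",
    "read_hits",
    "read_term_table",
]


def read_notes(path: str | Path) -> list[Note]:
    """Read notes from JSONL (one object per line) or TSV (with header)."""
    path = Path(path)
    notes = []
    if path.suffix.lower() in {".jsonl", ".json"}:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                notes.append(
                    Note(
                        patient_id=str(rec["patient_id"]),
                        date=rec.get("date", ""),
                        note_type=rec.get("note_type", ""),
                        text=rec.get("text", ""),
                    )
                )
    else:
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for row in frame.itertuples(index=False):
            notes.append(
                Note(
                    patient_id=str(row.patient_id),
                    date=getattr(row, "date", ""),
                    note_type=getattr(row, "note_type", ""),
                    text=getattr(row, "text", ""),
                )
            )
    return notes


def read_assigned(path: str | Path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [(str(r.patient_id), str(r.code)) for r in frame.itertuples(index=False)]


def read_term_table(path: str | Path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return [(str(r.code), str(r.term)) for r in frame.itertuples(index=False)]


def write_hits(path: str | Path, hits: list[MiningHit]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tnote_index\tsentence_index\tstart\tend\tterm\tcode\tstatus\n")
        for h in hits:
            fh.write(
                f"{h.patient_id}\t{h.note_index}\t{h.sentence_index}\t{h.start}\t{h.end}"
                f"\t{h.matched_term}\t{h.code}\t{h.status}\n"
            )


def read_hits(path: str | Path) -> list[MiningHit]:
    frame = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    return [
        MiningHit(
            patient_id=str(r.patient_id),
            note_index=int(r.note_index),
            sentence_index=int(r.sentence_index),
            start=int(r.start),
            end=int(r.end),
            matched_term=str(r.term),
            code=str(r.code),
            status=str(r.status),
        )
        for r in frame.itertuples(index=False)
    ]
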