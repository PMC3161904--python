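"""Mine the cohort's notes with the stepping longest-match algorithm.

Every candidate match is kept with its status (accepted, negated,
false-subject, blacklisted) so the disqualification counts are visible.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.config import default_blacklist, default_lexicons
from phenominer.icd10 import TermDictionary
from phenominer.io import read_notes, write_hits
from phenominer.mining import mine_corpus


def main() -> None:
    dictionary = TermDictionary.from_table(s.DICTIONARY_TSV, default_blacklist())
    notes = read_notes(s.DATA / "notes.jsonl")
    hits, summary = mine_corpus(notes, dictionary, default_lexicons())
    write_hits(s.HITS_TSV, hits)
    counts = Counter(summary.status_counts)
    print(f"{len(notes)} notes mined: {sum(counts.values())} candidate matches")
    for status, n in counts.most_common():
        print(f"  {status}: {n}")
    print(f"mean unique accepted codes per patient: {summary.mean_unique_codes:.2f}")
    print(f"written to {s.HITS_TSV}")


if __name__ == "__main__":
    main()
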