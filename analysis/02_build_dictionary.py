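"""Compile the matching dictionary from the cohort's term table.

Normalizes terms, rounds codes to level 3 and adds truncation variants
(specifier/comma/parenthesis rules); reports how many entries the variant
rules contribute.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.config import default_blacklist, default_specifiers
from phenominer.icd10 import build_dictionary
from phenominer.io import read_term_table


def main() -> None:
    table = read_term_table(s.DATA / "terms.tsv")
    dictionary = build_dictionary(table, default_specifiers(), default_blacklist())
    dictionary.to_table(s.DICTIONARY_TSV)
    n_variants = sum(1 for e in dictionary if e.origin == "variant")
    print(f"{len(table)} term rows -> {len(dictionary)} dictionary entries "
          f"({n_variants} rule-generated variants, {dictionary.skipped_codes} rows skipped)")
    print(f"written to {s.DICTIONARY_TSV}")


if __name__ == "__main__":
    main()
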