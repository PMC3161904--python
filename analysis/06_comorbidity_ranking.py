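"""Rank all code pairs, select candidates at FDR 1%, order the heatmap.

Candidates must co-occur more than (approximately) twice as often as
expected (comorbidity score >= 1) and survive Benjamini–Hochberg at
q = 0.01 over the full pair universe.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.comorbidity import bh_select, heatmap_order, pair_count, rank_all_pairs
from phenominer.matrix import AssociationMatrix


def main() -> None:
    matrix = AssociationMatrix.load(s.MATRIX_DIR)
    ranked = bh_select(rank_all_pairs(matrix), q=0.01, score_cutoff=1.0)
    ranked.to_csv(s.PAIRS_TSV, sep="\t", index=False)
    selected = ranked[ranked["selected"]]
    print(f"{pair_count(len(matrix.codes))} unordered pairs of {len(matrix.codes)} codes ranked")
    print(f"{len(selected)} candidate pairs selected (score >= 1.0, BH q < 0.01)")
    print("top candidates by comorbidity score:")
    for row in selected.head(5).itertuples(index=False):
        print(f"  {row.code_a}–{row.code_b}: obs {row.obs} vs expected {row.expt:.1f}, "
              f"score {row.score:.2f}, corrected p {row.corrected_p:.2e}")
    order, _ = heatmap_order(ranked, top_k=min(30, 2 * len(selected)))
    s.HEATMAP_ORDER_TXT.write_text("\n".join(order) + "\n")
    print(f"heatmap leaf order ({len(order)} codes) written to {s.HEATMAP_ORDER_TXT}")


if __name__ == "__main__":
    main()
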