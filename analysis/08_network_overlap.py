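"""Score shared PPI interactors for the planted disease pairs."""

import sys
from itertools import combinations
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.network_overlap import load_ppi, load_seed_map, score_pair


def main() -> None:
    ppi = load_ppi(s.PPI_TSV)
    seed_map = load_seed_map(s.SEEDS_TSV)
    frames = []
    for code_a, code_b in combinations(sorted(seed_map), 2):
        frame = score_pair(ppi, seed_map[code_a], seed_map[code_b], code_a, code_b)
        if len(frame):
            frames.append(frame)
    overlaps = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["code_a", "code_b", "gene", "degree", "seed_hits", "p"])
    )
    overlaps.to_csv(s.OVERLAPS_TSV, sep="\t", index=False)
    print(f"PPI: {ppi.number_of_nodes()} genes, {ppi.number_of_edges()} edges; "
          f"{len(seed_map)} diseases with seed genes")
    print(f"{len(overlaps)} shared-interactor candidates scored")
    for row in overlaps.sort_values('p').head(5).itertuples(index=False):
        print(f"  {row.code_a}–{row.code_b}: {row.gene} "
              f"({row.seed_hits}/{row.degree} partners are seeds, p = {row.p:.2e})")
    print(f"written to {s.OVERLAPS_TSV}")


if __name__ == "__main__":
    main()
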