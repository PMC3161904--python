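"""Chapter-level comorbidity network: frequencies and pairwise cosines."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.chapters import chapter_similarity, chapter_vectors
from phenominer.matrix import AssociationMatrix


def main() -> None:
    matrix = AssociationMatrix.load(s.MATRIX_DIR)
    network = chapter_similarity(chapter_vectors(matrix))
    network.save(s.CHAPTERS_GRAPHML, s.CHAPTERS_TSV)
    present = network.frequency[network.frequency > 0].sort_values(ascending=False)
    print("chapter frequencies (share of patient-chapter associations):")
    for chapter, freq in present.items():
        print(f"  {chapter}: {freq:.1%}")
    sim = network.similarity.copy()
    for ch in sim.index:
        sim.loc[ch, ch] = 0.0
    top = sim.stack().idxmax()
    print(f"most correlated chapter pair: {top[0]}–{top[1]} "
          f"(cosine {sim.loc[top]:.2f})")
    print(f"written to {s.CHAPTERS_GRAPHML} and {s.CHAPTERS_TSV}")


if __name__ == "__main__":
    main()
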