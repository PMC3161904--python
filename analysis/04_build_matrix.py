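"""Merge assigned and mined codes into the patient × ICD10 matrix."""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.io import read_assigned, read_hits
from phenominer.matrix import build_matrix
from phenominer.mining import ACCEPTED


def main() -> None:
    assigned = read_assigned(s.DATA / "assigned.tsv")
    accepted = [h for h in read_hits(s.HITS_TSV) if h.status == ACCEPTED]
    matrix = build_matrix(assigned, accepted)
    matrix.save(s.MATRIX_DIR)
    prov = matrix.provenance.tocoo()
    from collections import Counter

    shares = Counter({1: 0, 2: 0, 3: 0})
    shares.update(prov.data.tolist())
    total = max(sum(shares.values()), 1)
    print(f"matrix: {matrix.n_patients} patients x {len(matrix.codes)} codes, "
          f"{matrix.counts.nnz} nonzero cells")
    print(f"  assigned-only {shares[1] / total:.0%}, mined-only {shares[2] / total:.0%}, "
          f"both {shares[3] / total:.0%}")
    print(f"written to {s.MATRIX_DIR}/")


if __name__ == "__main__":
    main()
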