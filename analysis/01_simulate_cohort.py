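"""Generate the synthetic study cohort and PPI network with known truth.

Writes notes (JSONL), structured code assignments, the term table, the PPI
edge list with per-code seed genes, and the truth/ tables that the final
evaluation scores against.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.synthetic import (
    ClusterSpec,
    CohortConfig,
    make_cohort,
    make_dictionary,
    make_ppi,
    write_cohort,
)


def main() -> None:
    sdict = make_dictionary(s.N_CODES, seed=s.SEED)
    rng = np.random.default_rng(s.SEED + 1)
    prevalence = {
        c: float(rng.uniform(s.PREVALENCE_LOW, s.PREVALENCE_HIGH)) for c in sdict.codes
    }

    pair_codes = sdict.codes[: 2 * s.N_PLANTED_PAIRS]
    for c in pair_codes:
        prevalence[c] = s.PAIR_PREVALENCE
    pairs = [
        (pair_codes[2 * i], pair_codes[2 * i + 1], s.PLANTED_LIFT)
        for i in range(s.N_PLANTED_PAIRS)
    ]
    free = sdict.codes[2 * s.N_PLANTED_PAIRS :]
    clusters = []
    for k in range(s.N_CLUSTERS):
        block = free[10 * k : 10 * (k + 1)]
        clusters.append(ClusterSpec(s.CLUSTER_SIZE, block[0], tuple(block[1:])))

    config = CohortConfig(
        n_patients=s.N_PATIENTS,
        prevalence=prevalence,
        planted_pairs=pairs,
        cluster_spec=clusters,
        dominant_boost=s.DOMINANT_BOOST,
        seed=s.SEED,
    )
    notes, assigned, truth = make_cohort(config, sdict)
    write_cohort(s.DATA, notes, assigned, truth, sdict)

    ppi, seed_map, motifs = make_ppi(300, edge_prob=0.02, planted_motifs=3, seed=s.SEED)
    with open(s.PPI_TSV, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")
    with open(s.SEEDS_TSV, "w", encoding="utf-8") as fh:
        fh.write("code\tgene\n")
        for code in sorted(seed_map):
            for gene in sorted(seed_map[code]):
                fh.write(f"{code}\t{gene}\n")

    print(f"cohort: {s.N_PATIENTS} patients, {len(notes)} notes, {len(assigned)} assignments")
    print(f"planted: {len(pairs)} comorbid pairs at lift {s.PLANTED_LIFT}, "
          f"{len(clusters)} clusters of {s.CLUSTER_SIZE}")
    print(f"PPI: {ppi.number_of_nodes()} genes, {ppi.number_of_edges()} edges, "
          f"{len(motifs)} planted shared-interactor motifs")
    print(f"written under {s.DATA}")


if __name__ == "__main__":
    main()
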