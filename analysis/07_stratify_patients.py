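"""Stratify patients by TF-IDF cosine similarity and profile the clusters."""

import sys
from pathlib import Path

import networkx as nx

sys.path.insert(0, str(Path(__file__).parent))
import settings as s

from phenominer.config import default_excluded_codes
from phenominer.matrix import AssociationMatrix
from phenominer.stratification import stratify


def main() -> None:
    matrix = AssociationMatrix.load(s.MATRIX_DIR)
    result = stratify(
        matrix,
        min_codes=3,
        excluded_codes=tuple(default_excluded_codes()),
        cs_threshold=0.6,
        min_size=25,
    )
    s.STRATA_DIR.mkdir(parents=True, exist_ok=True)
    result.membership_frame().to_csv(s.STRATA_DIR / "clusters.tsv", sep="\t", index=False)
    with open(s.STRATA_DIR / "profiles.tsv", "w", encoding="utf-8") as fh:
        fh.write("cluster\tcode\tfraction\n")
        for cid, profile in enumerate(result.cluster_profiles):
            top10 = profile[profile > 0].sort_values(ascending=False).head(10)
            for code, frac in top10.items():
                fh.write(f"{cid}\t{code}\t{frac:.6f}\n")
    if result.network is not None:
        nx.write_graphml(result.network, str(s.STRATA_DIR / "patient_network.graphml"))

    print(f"{len(result.included_patients)} patients with >= 3 codes entered clustering")
    print(f"{len(result.clusters)} clusters with >= 25 members:")
    for cid, (members, top, profile) in enumerate(
        zip(result.clusters, result.top_codes, result.cluster_profiles)
    ):
        print(f"  cluster {cid}: {len(members)} members, "
              f"top code {top} ({profile[top]:.0%} of the pooled TF-IDF vector)")
    print(f"written to {s.STRATA_DIR}/")


if __name__ == "__main__":
    main()
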