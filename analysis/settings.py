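"""Shared study conditions and file locations for the analysis scripts.

One synthetic cohort stands in for the hospital corpus: 800 patients over
60 level-3 codes with uniformly drawn prevalences, three comorbid pairs
planted at lift 4, and three 40-patient clusters planted with a dominant
code plus nine support codes each.  Everything downstream of
01_simulate_cohort.py reads these files and writes its tables under
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

SEED = 1
N_PATIENTS = 800
N_CODES = 60
PREVALENCE_LOW = 0.01
PREVALENCE_HIGH = 0.08
N_PLANTED_PAIRS = 3
PLANTED_LIFT = 4.0
PAIR_PREVALENCE = 0.08
N_CLUSTERS = 3
CLUSTER_SIZE = 40
DOMINANT_BOOST = 5.0  # a cluster's hallmark code dominates its members' notes

DICTIONARY_TSV = RESULTS / "dictionary.tsv"
HITS_TSV = RESULTS / "hits.tsv"
MATRIX_DIR = RESULTS / "matrix"
CHAPTERS_GRAPHML = RESULTS / "chapters.graphml"
CHAPTERS_TSV = RESULTS / "chapters.tsv"
PAIRS_TSV = RESULTS / "pairs.tsv"
HEATMAP_ORDER_TXT = RESULTS / "heatmap_order.txt"
STRATA_DIR = RESULTS / "strata"
PPI_TSV = DATA / "ppi.tsv"
SEEDS_TSV = DATA / "seed_genes.tsv"
OVERLAPS_TSV = RESULTS / "overlaps.tsv"
EVALUATION_JSON = RESULTS / "evaluation.json"
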