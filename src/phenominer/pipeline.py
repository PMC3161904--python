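"""End-to-end pipeline orchestration with a reproducible run manifest.

Stages run in dependency order over plain-file intermediates (TSV / JSONL /
MatrixMarket / GraphML) so any stage can be rerun in isolation.  The
manifest records parameters, per-stage summary counts and sha256 hashes of
every written file; identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import comorbidity as cm
from . import io as pio
from .chapters import chapter_similarity, chapter_vectors
from .config import (
    default_blacklist,
    default_excluded_codes,
    default_lexicons,
    default_specifiers,
)
from .evaluation import evaluate_recovery
from .icd10 import TermDictionary, build_dictionary
from .matrix import AssociationMatrix, build_matrix
from .mining import ACCEPTED, mine_corpus
from .network_overlap import load_ppi, load_seed_map, score_pair
from .stratification import stratify
from .synthetic import CohortConfig, make_cohort, make_dictionary, make_ppi, write_cohort

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "build_dict",
    "mine",
    "matrix",
    "chapters",
    "comorbid",
    "stratify",
    "overlap",
    "evaluate",
)


@dataclass
class RunConfig:
    out_dir: str = "pipeline_out"
    seed: int = 0
    # simulate
    n_patients: int = 2000
    n_codes: int = 60
    prevalence_low: float = 0.01
    prevalence_high: float = 0.2
    planted_pairs: list = field(default_factory=list)  # [(a_idx, b_idx, lift)] by code index
    n_clusters: int = 0
    cluster_size: int = 30
    # mining / matrix
    min_codes: int = 3
    cs_threshold: float = 0.6
    min_size: int = 25
    q: float = 0.01
    score_cutoff: float = 1.0
    # overlap
    ppi_genes: int = 200
    ppi_edge_prob: float = 0.02
    ppi_motifs: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0,1)")
        if not 0 <= self.cs_threshold <= 1:
            raise ValueError("cs_threshold must be in [0,1]")
        if self.min_size < 1 or self.min_codes < 0:
            raise ValueError("min_size/min_codes out of range")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict.

    A stage failure aborts the run with the failing stage named; stages
    already completed keep their outputs and manifest entries.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "stages": {}, "files": {}}
    state: dict = {}

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "complete", "counts": counts}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)

    import numpy as np

    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            if stage == "simulate":
                sdict = make_dictionary(config.n_codes, seed=config.seed)
                rng = np.random.default_rng(config.seed + 1)
                prevalence = {
                    c: float(rng.uniform(config.prevalence_low, config.prevalence_high))
                    for c in sdict.codes
                }
                pairs = [
                    (sdict.codes[a], sdict.codes[b], float(lift))
                    for a, b, lift in config.planted_pairs
                ]
                from .synthetic import ClusterSpec

                clusters = []
                free = [c for c in sdict.codes if all(c not in p[:2] for p in pairs)]
                for k in range(config.n_clusters):
                    block = free[5 * k : 5 * k + 5]
                    if len(block) < 5:
                        raise ValueError("not enough codes for the requested clusters")
                    clusters.append(
                        ClusterSpec(size=config.cluster_size, dominant=block[0], support=tuple(block[1:]))
                    )
                cohort_cfg = CohortConfig(
                    n_patients=config.n_patients,
                    prevalence=prevalence,
                    planted_pairs=pairs,
                    cluster_spec=clusters,
                    seed=config.seed,
                )
                notes, assigned, truth = make_cohort(cohort_cfg, sdict)
                write_cohort(out / "data", notes, assigned, truth, sdict)
                state.update(notes=notes, assigned=assigned, truth=truth, sdict=sdict)
                record(
                    stage,
                    {"patients": config.n_patients, "notes": len(notes), "assigned": len(assigned)},
                    sorted((out / "data").rglob("*.tsv")) + [out / "data" / "notes.jsonl"],
                )
            elif stage == "build_dict":
                table = state.get("sdict").term_table if "sdict" in state else pio.read_term_table(out / "data" / "terms.tsv")
                dictionary = build_dictionary(table, default_specifiers(), default_blacklist())
                dictionary.to_table(out / "dictionary.tsv")
                state["dictionary"] = dictionary
                record(
                    stage,
                    {"entries": len(dictionary), "skipped": dictionary.skipped_codes},
                    [out / "dictionary.tsv"],
                )
            elif stage == "mine":
                dictionary = state.get("dictionary") or TermDictionary.from_table(
                    out / "dictionary.tsv", default_blacklist()
                )
                notes = state.get("notes") or pio.read_notes(out / "data" / "notes.jsonl")
                hits, summary = mine_corpus(notes, dictionary, default_lexicons())
                pio.write_hits(out / "hits.tsv", hits)
                state.update(hits=hits, notes=notes, dictionary=dictionary)
                record(
                    stage,
                    {
                        "matches": sum(summary.status_counts.values()),
                        **dict(summary.status_counts),
                        "mean_unique_codes": round(summary.mean_unique_codes, 3),
                    },
                    [out / "hits.tsv"],
                )
            elif stage == "matrix":
                hits = state.get("hits") or pio.read_hits(out / "hits.tsv")
                assigned = state.get("assigned") or pio.read_assigned(out / "data" / "assigned.tsv")
                accepted = [h for h in hits if h.status == ACCEPTED]
                mat = build_matrix(assigned, accepted)
                mat.save(out / "matrix")
                state["matrix"] = mat
                record(
                    stage,
                    {"patients": mat.n_patients, "codes": len(mat.codes)},
                    sorted((out / "matrix").glob("*")),
                )
            elif stage == "chapters":
                mat = state.get("matrix") or AssociationMatrix.load(out / "matrix")
                net = chapter_similarity(chapter_vectors(mat))
                net.save(out / "chapters.graphml", out / "chapters.tsv")
                state["matrix"] = mat
                record(
                    stage,
                    {"empty_chapters": len(net.empty_chapters)},
                    [out / "chapters.graphml", out / "chapters.tsv"],
                )
            elif stage == "comorbid":
                mat = state.get("matrix") or AssociationMatrix.load(out / "matrix")
                pairs = cm.bh_select(
                    cm.rank_all_pairs(mat), q=config.q, score_cutoff=config.score_cutoff
                )
                pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
                state.update(matrix=mat, pairs=pairs)
                record(
                    stage,
                    {"pairs": len(pairs), "selected": int(pairs["selected"].sum())},
                    [out / "pairs.tsv"],
                )
            elif stage == "stratify":
                mat = state.get("matrix") or AssociationMatrix.load(out / "matrix")
                result = stratify(
                    mat,
                    min_codes=config.min_codes,
                    excluded_codes=tuple(default_excluded_codes()),
                    cs_threshold=config.cs_threshold,
                    min_size=config.min_size,
                )
                result.membership_frame().to_csv(out / "clusters.tsv", sep="\t", index=False)
                state.update(matrix=mat, strata=result)
                record(
                    stage,
                    {"included": len(result.included_patients), "clusters": len(result.clusters)},
                    [out / "clusters.tsv"],
                )
            elif stage == "overlap":
                ppi, seed_map, motifs = make_ppi(
                    config.ppi_genes, config.ppi_edge_prob, config.ppi_motifs, seed=config.seed
                )
                frames = []
                for code_a, code_b, *_ in motifs:
                    frames.append(score_pair(ppi, seed_map[code_a], seed_map[code_b], code_a, code_b))
                import pandas as pd

                overlaps = (
                    pd.concat(frames, ignore_index=True)
                    if frames
                    else pd.DataFrame(columns=["code_a", "code_b", "gene", "degree", "seed_hits", "p"])
                )
                overlaps.to_csv(out / "overlaps.tsv", sep="\t", index=False)
                state["overlaps"] = overlaps
                record(stage, {"candidates": len(overlaps)}, [out / "overlaps.tsv"])
            elif stage == "evaluate":
                truth = state.get("truth")
                if truth is None:
                    raise ValueError("evaluate requires the simulate stage in the same run")
                hits = state.get("hits") or pio.read_hits(out / "hits.tsv")
                pairs = state.get("pairs")
                selected = pairs[pairs["selected"]] if pairs is not None else None
                strata = state.get("strata")
                report = evaluate_recovery(
                    truth,
                    hits=hits,
                    selected_pairs=selected,
                    recovered_clusters=strata.clusters if strata is not None else None,
                )
                summary = {
                    "incidence_precision": report.mining.incidence_precision,
                    "association_precision": report.mining.association_precision,
                    "negation_precision": report.mining.negation_precision,
                    "negation_recall": report.mining.negation_recall,
                    "mention_recall": report.mining.mention_recall,
                    "pair_recall": report.pair_recall,
                    "pair_fdr": report.pair_fdr,
                    "ari": report.ari,
                }
                (out / "evaluation.json").write_text(json.dumps(summary, indent=2))
                record(stage, {k: round(v, 4) for k, v in summary.items() if v == v}, [out / "evaluation.json"])
        except Exception as exc:  # noqa: BLE001 - abort naming the stage
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
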