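"""Evaluation of pipeline output against ground truth.

Mirrors the manual-curation style of assessment: *incidence precision*
judges every individual mining hit; *association precision* counts each
patient–code association once and calls it correct if at least one of its
incidences is correct.  The negation module is assessed by the share of its
disqualifications that were truly negated/other-subject mentions
(precision) and the share of all such mentions it caught (recall).  Cohort-
level recovery adds comorbidity precision/recall/empirical FDR against
planted pairs and the adjusted Rand index against planted cluster labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .icd10 import chapter_of
from .mining import ACCEPTED, FALSE_SUBJECT, NEGATED, MiningHit
from .synthetic import CohortTruth

__all__ = [
    "precision",
    "PrecisionReport",
    "evaluate_against_truth",
    "RecoveryReport",
    "evaluate_recovery",
]


def precision(correct: int, false: int) -> float:
    """True positives over all positives; 0 when nothing was judged."""
    total = correct + false
    return correct / total if total else 0.0


@dataclass
class PrecisionReport:
    per_chapter: pd.DataFrame  # chapter, inc_correct, inc_false, inc_precision, assoc_*
    incidence_precision: float = 0.0
    association_precision: float = 0.0
    negation_precision: float = 0.0
    negation_recall: float = 0.0
    mention_recall: float = 0.0  # truth mentions (any label) matched by some hit
    negated_disqualified_rate: float = 0.0  # planted negated/subject mentions disqualified
    counts: dict = field(default_factory=dict)


def _truth_lookup(truth: CohortTruth) -> dict[tuple[str, int, int, int], tuple[str, str]]:
    out = {}
    for row in truth.mentions.itertuples(index=False):
        out[(row.patient_id, int(row.note_index), int(row.start), int(row.end))] = (
            row.code,
            row.label,
        )
    return out


def evaluate_against_truth(hits: list[MiningHit], truth: CohortTruth) -> PrecisionReport:
    """Judge mining hits against planted mention truth.

    A hit is correct when a truth mention with the same span and code is
    labelled ``true_hit``; accidental matches (no truth record) are false.
    Hits for patients absent from the truth are an error.
    """
    known_patients = set(truth.true_codes)
    lookup = _truth_lookup(truth)

    inc = {}  # chapter -> [correct, false]
    assoc_any_correct: dict[tuple[str, str], bool] = {}
    disq_correct = disq_false = 0
    missed_negations = 0  # accepted hits that were truly negated/subject mentions
    matched_keys = set()

    for h in hits:
        if h.patient_id not in known_patients:
            raise ValueError(f"hit references unknown patient {h.patient_id!r}")
        key = (h.patient_id, h.note_index, h.start, h.end)
        rec = lookup.get(key)
        if rec is not None and rec[0] == h.code:
            matched_keys.add(key)
            label = rec[1]
        else:
            label = None  # accidental match
        if h.status == ACCEPTED:
            ok = label == "true_hit"
            ch = chapter_of(h.code)
            inc.setdefault(ch, [0, 0])[0 if ok else 1] += 1
            a_key = (h.patient_id, h.code)
            assoc_any_correct[a_key] = assoc_any_correct.get(a_key, False) or ok
            if label in (NEGATED, FALSE_SUBJECT):
                missed_negations += 1
        elif h.status in (NEGATED, FALSE_SUBJECT):
            if label in (NEGATED, FALSE_SUBJECT):
                disq_correct += 1
            else:
                disq_false += 1

    rows = []
    for ch in sorted(inc):
        c, f = inc[ch]
        a_c = sum(1 for (p, code), ok in assoc_any_correct.items() if ok and chapter_of(code) == ch)
        a_f = sum(
            1 for (p, code), ok in assoc_any_correct.items() if not ok and chapter_of(code) == ch
        )
        rows.append(
            {
                "chapter": ch,
                "inc_correct": c,
                "inc_false": f,
                "inc_precision": precision(c, f),
                "assoc_correct": a_c,
                "assoc_false": a_f,
                "assoc_precision": precision(a_c, a_f),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "chapter",
            "inc_correct",
            "inc_false",
            "inc_precision",
            "assoc_correct",
            "assoc_false",
            "assoc_precision",
        ],
    )
    inc_c = int(frame["inc_correct"].sum()) if len(frame) else 0
    inc_f = int(frame["inc_false"].sum()) if len(frame) else 0
    as_c = sum(1 for ok in assoc_any_correct.values() if ok)
    as_f = sum(1 for ok in assoc_any_correct.values() if not ok)

    n_mentions = len(truth.mentions)
    n_matched = len(matched_keys)
    truly_neg = truth.mentions["label"].isin([NEGATED, FALSE_SUBJECT])
    neg_keys = {
        (r.patient_id, int(r.note_index), int(r.start), int(r.end))
        for r in truth.mentions[truly_neg].itertuples(index=False)
    }
    neg_caught_rate = (
        disq_correct / len(neg_keys & matched_keys) if neg_keys & matched_keys else 0.0
    )
    return PrecisionReport(
        per_chapter=frame,
        incidence_precision=precision(inc_c, inc_f),
        association_precision=precision(as_c, as_f),
        negation_precision=precision(disq_correct, disq_false),
        negation_recall=precision(disq_correct, missed_negations),
        mention_recall=n_matched / n_mentions if n_mentions else 0.0,
        negated_disqualified_rate=neg_caught_rate,
        counts={
            "inc_correct": inc_c,
            "inc_false": inc_f,
            "assoc_correct": as_c,
            "assoc_false": as_f,
            "disq_correct": disq_correct,
            "disq_false": disq_false,
            "missed_negations": missed_negations,
            "truth_mentions": n_mentions,
            "truth_mentions_matched": n_matched,
        },
    )


@dataclass
class RecoveryReport:
    mining: PrecisionReport | None = None
    pair_precision: float = 0.0
    pair_recall: float = 0.0
    pair_fdr: float = 0.0
    ari: float = float("nan")
    counts: dict = field(default_factory=dict)


def evaluate_recovery(
    truth: CohortTruth,
    hits: list[MiningHit] | None = None,
    selected_pairs: pd.DataFrame | None = None,
    recovered_clusters: list[set[str]] | None = None,
) -> RecoveryReport:
    """Cohort-level recovery metrics for whichever outputs are supplied.

    Comorbidity: planted pairs are the positives; the empirical FDR is
    false discoveries / max(discoveries, 1).  Clustering: ARI between
    recovered and planted labels over the planted-cluster patients (a
    planted patient missing from every recovered cluster keeps a unique
    singleton label).
    """
    report = RecoveryReport()
    if hits is not None:
        report.mining = evaluate_against_truth(hits, truth)
    if selected_pairs is not None:
        planted = {tuple(sorted((a, b))) for a, b, _ in truth.planted_pairs}
        if len(selected_pairs):
            found = {
                tuple(sorted((r.code_a, r.code_b)))
                for r in selected_pairs.itertuples(index=False)
            }
        else:
            found = set()
        tp = len(found & planted)
        report.pair_precision = tp / len(found) if found else 0.0
        report.pair_recall = tp / len(planted) if planted else 0.0
        report.pair_fdr = (len(found) - tp) / max(len(found), 1)
        report.counts.update(
            {"pairs_planted": len(planted), "pairs_found": len(found), "pairs_tp": tp}
        )
    if recovered_clusters is not None:
        planted_patients = sorted(truth.cluster_labels)
        if planted_patients:
            recovered_of: dict[str, int] = {}
            for cid, members in enumerate(recovered_clusters):
                for pid in members:
                    recovered_of[pid] = cid
            next_singleton = len(recovered_clusters)
            rec_labels = []
            for pid in planted_patients:
                if pid in recovered_of:
                    rec_labels.append(recovered_of[pid])
                else:
                    rec_labels.append(next_singleton)
                    next_singleton += 1
            true_labels = [truth.cluster_labels[pid] for pid in planted_patients]
            report.ari = float(adjusted_rand_score(true_labels, rec_labels))
            report.counts["planted_cluster_patients"] = len(planted_patients)
    return report
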