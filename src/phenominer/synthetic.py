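"""Synthetic cohorts with known ground truth.

Every pipeline stage is exercised against generated data because the kind
of hospital corpus this pipeline targets cannot be shared.  The generator
emulates the features the pipeline reacts to — per-code prevalence, planted
pairwise co-occurrence lifts, dictionary-term mentions embedded in free
text, negation and false-subject sentence prefixes, cluster-structured
patients, and PPI networks with planted shared interactors — and records
the truth (true codes, mention spans with labels, planted pairs, cluster
labels) so precision, recall, FDR and ARI can be measured exactly.

The notes are synthetic token salad rather than natural clinical language:
the miner is exact-match and language-agnostic by design, so nothing in the
pipeline depends on grammar.  Term words, filler words and lexicon words
are drawn from disjoint pools so no accidental dictionary matches occur
unless a test plants them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .config import default_lexicons, default_specifiers
from .mining import Note

__all__ = [
    "ClusterSpec",
    "CohortConfig",
    "CohortTruth",
    "SyntheticDictionary",
    "make_dictionary",
    "make_cohort",
    "make_ppi",
    "write_cohort",
]

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu ka ke ki ko ku "
    "la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra re ri ro ru "
    "sa se si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()

# Letters whose full 00–99 digit span lies inside one chapter range.
_SAFE_LETTERS = "ACFGJLMNRZ"


def _word_stream(rng: np.random.Generator, forbidden: set[str]):
    """Yield unique pseudo-words, never colliding with ``forbidden``."""
    seen = set(forbidden)
    while True:
        n_syl = int(rng.integers(2, 4))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(n_syl))
        if word not in seen:
            seen.add(word)
            yield word


@dataclass
class SyntheticDictionary:
    """A generated term table plus the normalized terms usable as mentions."""

    term_table: list[tuple[str, str]]  # (code, raw term) rows
    codes: list[str]
    terms_by_code: dict[str, list[str]]  # normalized mention terms
    filler_words: list[str]  # disjoint from every term word


def make_dictionary(
    n_codes: int, terms_per_code: int = 2, seed: int = 0, n_filler_words: int = 60
) -> SyntheticDictionary:
    """Generate a synthetic ICD10 term table.

    Multi-word terms are unique across codes (term words are never reused),
    level-3 codes span several chapters, and every fourth code receives an
    extra specifier-bearing term ("... caused by ...") so rule-based variant
    generation is exercised downstream.  Deterministic in ``seed``.
    """
    if n_codes < 1:
        raise ValueError("n_codes must be >= 1")
    rng = np.random.default_rng(seed)
    lex = default_lexicons()
    forbidden = set(lex.negations) | set(lex.subjects)
    for phrase in default_specifiers():
        forbidden.update(phrase.split())
    words = _word_stream(rng, forbidden)

    codes: list[str] = []
    seen_codes: set[str] = set()
    while len(codes) < n_codes:
        code = f"{_SAFE_LETTERS[int(rng.integers(len(_SAFE_LETTERS)))]}{int(rng.integers(100)):02d}"
        if code not in seen_codes:
            seen_codes.add(code)
            codes.append(code)

    table: list[tuple[str, str]] = []
    terms_by_code: dict[str, list[str]] = {}
    for k, code in enumerate(codes):
        terms = []
        for _ in range(terms_per_code):
            term = f"{next(words)} {next(words)}"
            terms.append(term)
            table.append((code, term))
        if k % 4 == 0:
            full = f"{next(words)} {next(words)} caused by {next(words)}"
            terms.append(full)
            table.append((code, full))
        terms_by_code[code] = terms
    filler = [next(words) for _ in range(n_filler_words)]
    return SyntheticDictionary(
        term_table=table, codes=codes, terms_by_code=terms_by_code, filler_words=filler
    )


@dataclass(frozen=True)
class ClusterSpec:
    size: int
    dominant: str
    support: tuple[str, ...] = ()


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Rates are calibrated to the corpus-level statistics a psychiatric-
    hospital EPR corpus exhibits: roughly one in ten candidate matches is
    negated, false-subject mentions are an order of magnitude rarer, and
    about a quarter of a patient's codes also appear as structured
    assignments.
    """

    n_patients: int = 2000
    prevalence: dict[str, float] = field(default_factory=dict)  # code -> Bernoulli p
    planted_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    cluster_spec: list[ClusterSpec] = field(default_factory=list)
    mention_rate: float = 2.0  # Poisson mean mentions per true code
    negation_rate: float = 0.10
    false_subject_rate: float = 0.015
    assigned_rate: float = 0.25
    distractor_rate: float = 1.0  # distractor sentences per mention sentence
    dominant_boost: float = 3.0  # mention-rate multiplier for a cluster's dominant code
    sentences_per_note: int = 6
    seed: int = 0

    def validate(self) -> None:
        for code, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {code} outside [0,1]: {p}")
        for r in (self.negation_rate, self.false_subject_rate, self.assigned_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate outside [0,1]: {r}")
        if self.negation_rate + self.false_subject_rate > 1.0:
            raise ValueError("negation_rate + false_subject_rate exceeds 1")
        in_pair: set[str] = set()
        for a, b, lift in self.planted_pairs:
            if lift < 0:
                raise ValueError(f"negative lift for pair ({a}, {b})")
            for c in (a, b):
                if c in in_pair:
                    raise ValueError(f"code {c} appears in more than one planted pair")
                if c not in self.prevalence:
                    raise ValueError(f"planted-pair code {c} has no prevalence")
                in_pair.add(c)


@dataclass
class CohortTruth:
    true_codes: dict[str, set[str]]  # patient -> codes
    mentions: pd.DataFrame  # patient_id note_index start end term code label
    planted_pairs: list[tuple[str, str, float]]
    cluster_labels: dict[str, int]  # planted members only

    def mentions_for(self, patient_id: str) -> pd.DataFrame:
        return self.mentions[self.mentions["patient_id"] == patient_id]


def _sample_true_codes(config: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    codes = sorted(config.prevalence)
    idx = {c: j for j, c in enumerate(codes)}
    n = config.n_patients
    x = np.zeros((n, len(codes)), dtype=bool)
    paired = {c for a, b, _ in config.planted_pairs for c in (a, b)}
    for c in codes:
        if c not in paired:
            x[:, idx[c]] = rng.random(n) < config.prevalence[c]
    for a, b, lift in config.planted_pairs:
        pa, pb = config.prevalence[a], config.prevalence[b]
        joint = lift * pa * pb
        p00 = 1.0 - pa - pb + joint
        if joint > min(pa, pb) + 1e-12 or p00 < -1e-12:
            raise ValueError(
                f"infeasible 2x2 for planted pair ({a}, {b}): lift {lift} with "
                f"prevalences {pa}, {pb}"
            )
        # categories along u: [0, c0) both, [c0, c1) a-only, [c1, c2) b-only
        cum = np.cumsum([joint, pa - joint, pb - joint])
        u = rng.random(n)
        x[:, idx[a]] = u < cum[1]
        x[:, idx[b]] = (u < cum[0]) | ((u >= cum[1]) & (u < cum[2]))
    return x


def make_cohort(
    config: CohortConfig, dictionary: SyntheticDictionary
) -> tuple[list[Note], list[tuple[str, str]], CohortTruth]:
    """Generate notes, assigned codes and ground truth for one cohort.

    True codes are independent Bernoulli draws per prevalence; each planted
    pair's 2×2 is constructed directly with joint probability lift·p_a·p_b
    and preserved marginals.  Cluster members additionally receive their
    dominant and support codes.  Every true code is mentioned in note text
    Poisson(mention_rate) times; each mention is prefixed with a negation or
    subject token at the configured rates and labelled accordingly in the
    truth.  A random assigned_rate subset of true codes is also written as
    structured assignments.  Byte-identical output for identical
    config+seed.
    """
    config.validate()
    unknown = set(config.prevalence) - set(dictionary.codes)
    unknown |= {
        c
        for spec in config.cluster_spec
        for c in (spec.dominant, *spec.support)
        if c not in dictionary.codes
    }
    if unknown:
        raise ValueError(f"codes without dictionary terms: {sorted(unknown)}")
    rng = np.random.default_rng(config.seed)
    lex = default_lexicons()
    neg_words = sorted(lex.negations)
    subj_words = sorted(lex.subjects)
    filler = dictionary.filler_words
    codes = sorted(config.prevalence)
    x = _sample_true_codes(config, rng)

    # plant clusters on disjoint random member sets
    labels = np.full(config.n_patients, -1, dtype=int)
    total_members = sum(s.size for s in config.cluster_spec)
    if total_members > config.n_patients:
        raise ValueError("cluster sizes exceed the cohort")
    order = rng.permutation(config.n_patients)
    cursor = 0
    cluster_codes: dict[int, ClusterSpec] = {}
    extra_true: dict[int, set[str]] = {}
    dominant_of: dict[int, str] = {}
    for cid, spec in enumerate(config.cluster_spec):
        members = order[cursor : cursor + spec.size]
        cursor += spec.size
        labels[members] = cid
        cluster_codes[cid] = spec
        for m in members:
            extra_true[int(m)] = {spec.dominant, *spec.support}
            dominant_of[int(m)] = spec.dominant

    code_idx = {c: j for j, c in enumerate(codes)}
    notes: list[Note] = []
    assigned: list[tuple[str, str]] = []
    mention_rows: list[dict] = []
    true_codes: dict[str, set[str]] = {}
    cluster_labels: dict[str, int] = {}
    note_counter = 0

    for p in range(config.n_patients):
        pid = f"P{p:05d}"
        truths = {codes[j] for j in np.where(x[p])[0]}
        truths |= extra_true.get(p, set())
        true_codes[pid] = truths
        if labels[p] >= 0:
            cluster_labels[pid] = int(labels[p])

        # mention sentences: (tokens, term_pos, term_width, term, code, label)
        sentences: list[tuple[list[str], int, int, str, str, str]] = []
        for code in sorted(truths):
            lam = config.mention_rate
            if dominant_of.get(p) == code:
                lam *= config.dominant_boost
            for _ in range(int(rng.poisson(lam))):
                u = rng.random()
                if u < config.negation_rate:
                    label = "negated"
                    prefix = [neg_words[int(rng.integers(len(neg_words)))]]
                elif u < config.negation_rate + config.false_subject_rate:
                    label = "false_subject"
                    prefix = [subj_words[int(rng.integers(len(subj_words)))]]
                else:
                    label = "true_hit"
                    prefix = [filler[int(rng.integers(len(filler)))] for _ in range(int(rng.integers(1, 3)))]
                terms = dictionary.terms_by_code[code]
                term = terms[int(rng.integers(len(terms)))]
                suffix = [filler[int(rng.integers(len(filler)))] for _ in range(int(rng.integers(0, 3)))]
                tokens = prefix + term.split() + suffix
                sentences.append((tokens, len(prefix), len(term.split()), term, code, label))
        n_distract = int(rng.poisson(config.distractor_rate * max(len(sentences), 1)))
        for _ in range(n_distract):
            tokens = [filler[int(rng.integers(len(filler)))] for _ in range(int(rng.integers(3, 7)))]
            sentences.append((tokens, -1, 0, "", "", ""))
        sentences = [sentences[i] for i in rng.permutation(len(sentences))]

        # chunk into notes, assembling text with exact mention offsets
        spn = config.sentences_per_note
        for chunk_start in range(0, len(sentences), spn):
            chunk = sentences[chunk_start : chunk_start + spn]
            parts: list[str] = []
            cursor_chars = 0
            local_index = note_counter
            for tokens, pos, width, term, code, label in chunk:
                sent = " ".join(tokens)
                if pos >= 0:
                    before = " ".join(tokens[:pos])
                    start = cursor_chars + len(before) + (1 if before else 0)
                    end = start + len(" ".join(tokens[pos : pos + width]))
                    mention_rows.append(
                        {
                            "patient_id": pid,
                            "note_index": local_index,
                            "start": start,
                            "end": end,
                            "term": term,
                            "code": code,
                            "label": label,
                        }
                    )
                parts.append(sent)
                cursor_chars += len(sent) + 2  # ". " joins sentences
            text = ". ".join(parts) + "." if parts else ""
            notes.append(Note(patient_id=pid, date="2020-01-01", note_type="treatment note", text=text))
            note_counter += 1

        for code in sorted(truths):
            if rng.random() < config.assigned_rate:
                assigned.append((pid, code))

    mentions = pd.DataFrame(
        mention_rows,
        columns=["patient_id", "note_index", "start", "end", "term", "code", "label"],
    )
    truth = CohortTruth(
        true_codes=true_codes,
        mentions=mentions,
        planted_pairs=list(config.planted_pairs),
        cluster_labels=cluster_labels,
    )
    return notes, assigned, truth


def make_ppi(
    n_genes: int,
    edge_prob: float,
    planted_motifs: int = 0,
    seed: int = 0,
    motif_codes: list[tuple[str, str]] | None = None,
) -> tuple[nx.Graph, dict[str, set[str]], list[tuple[str, str, str, str, str]]]:
    """Erdős–Rényi PPI background with planted seed_a—candidate—seed_b motifs.

    Returns (graph, code→seed-gene map, motifs) where each motif records
    (code_a, code_b, seed_a, candidate, seed_b).  Motif genes are distinct
    and reserved: background edges never touch two motif genes of the same
    motif, so the planted candidate's adjacency to both seeds is never
    accidental.  Deterministic in ``seed``.
    """
    if n_genes < 3:
        raise ValueError("n_genes must be >= 3")
    if 3 * planted_motifs > n_genes:
        raise ValueError("not enough genes for the requested motifs")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    g = nx.Graph()
    g.add_nodes_from(genes)
    if edge_prob > 0:
        upper = np.triu_indices(n_genes, k=1)
        mask = rng.random(len(upper[0])) < edge_prob
        for i, j in zip(upper[0][mask], upper[1][mask]):
            g.add_edge(genes[i], genes[j])
    motifs = []
    seed_map: dict[str, set[str]] = {}
    reserved = rng.permutation(n_genes)[: 3 * planted_motifs]
    for k in range(planted_motifs):
        sa, cand, sb = (genes[reserved[3 * k + d]] for d in range(3))
        g.add_edge(sa, cand)
        g.add_edge(cand, sb)
        if g.has_edge(sa, sb):
            g.remove_edge(sa, sb)
        if motif_codes and k < len(motif_codes):
            code_a, code_b = motif_codes[k]
        else:
            code_a, code_b = f"M{2 * k % 100:02d}", f"N{(2 * k + 1) % 100:02d}"
        seed_map.setdefault(code_a, set()).add(sa)
        seed_map.setdefault(code_b, set()).add(sb)
        motifs.append((code_a, code_b, sa, cand, sb))
    return g, seed_map, motifs


def write_cohort(
    directory: str | Path,
    notes: list[Note],
    assigned: list[tuple[str, str]],
    truth: CohortTruth,
    dictionary: SyntheticDictionary | None = None,
) -> None:
    """Write a cohort in the formats the pipeline consumes, plus truth/."""
    directory = Path(directory)
    (directory / "truth").mkdir(parents=True, exist_ok=True)
    with open(directory / "notes.jsonl", "w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {"patient_id": n.patient_id, "date": n.date, "note_type": n.note_type, "text": n.text},
                    ensure_ascii=False,
                )
                + "\n"
            )
    with open(directory / "assigned.tsv", "w", encoding="utf-8") as fh:
        fh.write("patient_id\tcode\n")
        for pid, code in assigned:
            fh.write(f"{pid}\t{code}\n")
    truth.mentions.to_csv(directory / "truth" / "mentions.tsv", sep="\t", index=False)
    with open(directory / "truth" / "true_codes.tsv", "w", encoding="utf-8") as fh:
        fh.write("patient_id\tcode\n")
        for pid in sorted(truth.true_codes):
            for code in sorted(truth.true_codes[pid]):
                fh.write(f"{pid}\t{code}\n")
    with open(directory / "truth" / "clusters.tsv", "w", encoding="utf-8") as fh:
        fh.write("patient_id\tcluster\n")
        for pid in sorted(truth.cluster_labels):
            fh.write(f"{pid}\t{truth.cluster_labels[pid]}\n")
    with open(directory / "truth" / "planted_pairs.tsv", "w", encoding="utf-8") as fh:
        fh.write("code_a\tcode_b\tlift\n")
        for a, b, lift in truth.planted_pairs:
            fh.write(f"{a}\t{b}\t{lift}\n")
    if dictionary is not None:
        with open(directory / "terms.tsv", "w", encoding="utf-8") as fh:
            fh.write("code\tterm\n")
            for code, term in dictionary.term_table:
                fh.write(f"{code}\t{term}\n")
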