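import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from phenominer.evaluation import evaluate_recovery
from phenominer.icd10 import chapter_of, is_level3
from phenominer.network_overlap import first_order_network, shared_interactors
from phenominer.synthetic import (
    ClusterSpec,
    CohortConfig,
    CohortTruth,
    make_cohort,
    make_dictionary,
    make_ppi,
    write_cohort,
)


def dir_hashes(directory):
    out = {}
    for path in sorted(Path(directory).rglob("*")):
        if path.is_file():
            out[str(path.relative_to(directory))] = hashlib.sha256(path.read_bytes()).hexdigest()
    return out


class TestMakeDictionary:
    def test_single_code_single_term(self):
        d = make_dictionary(1, terms_per_code=1, seed=0)
        assert len(d.codes) == 1

    def test_deterministic(self):
        a = make_dictionary(12, seed=4)
        b = make_dictionary(12, seed=4)
        assert a.term_table == b.term_table and a.filler_words == b.filler_words

    def test_many_codes_span_chapters(self):
        d = make_dictionary(50, seed=1)
        assert len(set(d.codes)) == 50
        assert all(is_level3(c) for c in d.codes)
        assert len({chapter_of(c) for c in d.codes}) >= 3

    def test_term_words_unique_across_codes(self):
        d = make_dictionary(30, seed=2)
        words = [
            w
            for _, term in d.term_table
            for w in term.split()
            if w not in {"caused", "by"}
        ]
        assert len(words) == len(set(words))


class TestMakeCohort:
    def config(self, sdict, **kw):
        defaults = dict(n_patients=300, prevalence={c: 0.1 for c in sdict.codes}, seed=5)
        defaults.update(kw)
        return CohortConfig(**defaults)

    def test_deterministic_files(self, tmp_path):
        d = make_dictionary(10, seed=0)
        for sub in ("a", "b"):
            cfg = self.config(d)
            write_cohort(tmp_path / sub, *make_cohort(cfg, d), d)
        assert dir_hashes(tmp_path / "a") == dir_hashes(tmp_path / "b")

    def test_noise_free_labels_all_true(self):
        d = make_dictionary(8, seed=1)
        cfg = self.config(d, negation_rate=0.0, false_subject_rate=0.0)
        _, _, truth = make_cohort(cfg, d)
        assert set(truth.mentions["label"]) == {"true_hit"}

    def test_marginal_prevalence_within_three_se(self):
        d = make_dictionary(10, seed=2)
        n, p = 2000, 0.1
        cfg = self.config(d, n_patients=n, prevalence={c: p for c in d.codes})
        _, _, truth = make_cohort(cfg, d)
        se = np.sqrt(p * (1 - p) / n)
        for code in d.codes:
            freq = sum(code in s for s in truth.true_codes.values()) / n
            assert abs(freq - p) <= 3 * se

    def test_planted_joint_within_three_se(self):
        d = make_dictionary(10, seed=3)
        n, p, lift = 5000, 0.1, 3.0
        a, b = d.codes[0], d.codes[1]
        cfg = self.config(
            d, n_patients=n, prevalence={c: p for c in d.codes}, planted_pairs=[(a, b, lift)]
        )
        _, _, truth = make_cohort(cfg, d)
        joint = lift * p * p
        freq = sum((a in s) and (b in s) for s in truth.true_codes.values()) / n
        assert abs(freq - joint) <= 3 * np.sqrt(joint * (1 - joint) / n)
        # marginals preserved despite the lift
        for c in (a, b):
            fc = sum(c in s for s in truth.true_codes.values()) / n
            assert abs(fc - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_unit_lift_keeps_codes_independent(self):
        d = make_dictionary(6, seed=4)
        n, p = 5000, 0.2
        a, b = d.codes[0], d.codes[1]
        cfg = self.config(
            d, n_patients=n, prevalence={c: p for c in d.codes}, planted_pairs=[(a, b, 1.0)]
        )
        _, _, truth = make_cohort(cfg, d)
        n11 = sum((a in s) and (b in s) for s in truth.true_codes.values())
        n10 = sum((a in s) and (b not in s) for s in truth.true_codes.values())
        n01 = sum((a not in s) and (b in s) for s in truth.true_codes.values())
        n00 = n - n11 - n10 - n01
        odds_ratio = (n11 * n00) / max(n10 * n01, 1)
        assert 0.75 <= odds_ratio <= 1.33

    def test_infeasible_lift_rejected(self):
        d = make_dictionary(4, seed=5)
        cfg = self.config(
            d,
            prevalence={c: 0.5 for c in d.codes},
            planted_pairs=[(d.codes[0], d.codes[1], 4.0)],
        )
        with pytest.raises(ValueError, match="infeasible"):
            make_cohort(cfg, d)

    def test_cluster_members_get_their_codes(self):
        d = make_dictionary(12, seed=6)
        spec = ClusterSpec(size=20, dominant=d.codes[0], support=tuple(d.codes[1:4]))
        cfg = self.config(d, cluster_spec=[spec])
        _, _, truth = make_cohort(cfg, d)
        members = [p for p, c in truth.cluster_labels.items() if c == 0]
        assert len(members) == 20
        for pid in members:
            assert {spec.dominant, *spec.support} <= truth.true_codes[pid]

    def test_mention_spans_resolve_in_notes(self):
        d = make_dictionary(8, seed=7)
        notes, _, truth = make_cohort(self.config(d), d)
        for row in truth.mentions.head(100).itertuples(index=False):
            text = notes[row.note_index].text
            assert text[row.start : row.end] == row.term


class TestMakePpi:
    def test_pure_motif_has_two_edges(self):
        g, seed_map, motifs = make_ppi(10, edge_prob=0.0, planted_motifs=1, seed=0)
        assert g.number_of_edges() == 2 and len(motifs) == 1

    def test_deterministic(self):
        a = make_ppi(50, 0.05, 2, seed=3)
        b = make_ppi(50, 0.05, 2, seed=3)
        assert set(a[0].edges) == set(b[0].edges) and a[1] == b[1]

    def test_planted_candidate_recovered_by_shared_interactors(self):
        g, seed_map, motifs = make_ppi(80, 0.02, 2, seed=8)
        for code_a, code_b, _, cand, _ in motifs:
            na = first_order_network(g, seed_map[code_a], code_a)
            nb = first_order_network(g, seed_map[code_b], code_b)
            assert cand in shared_interactors(na, nb, g)


class TestEvaluateRecovery:
    def truth(self):
        return CohortTruth(
            true_codes={"p0": {"A00"}, "p1": {"A01"}},
            mentions=pd.DataFrame(
                columns=["patient_id", "note_index", "start", "end", "term", "code", "label"]
            ),
            planted_pairs=[("A00", "A01", 4.0), ("A02", "A03", 4.0)],
            cluster_labels={"p0": 0, "p1": 1},
        )

    def test_half_recovered_pairs(self):
        selected = pd.DataFrame({"code_a": ["A00"], "code_b": ["A01"]})
        report = evaluate_recovery(self.truth(), selected_pairs=selected)
        assert report.pair_recall == 0.5 and report.pair_fdr == 0.0

    def test_empty_output_zero_recall_zero_fdr(self):
        selected = pd.DataFrame(columns=["code_a", "code_b"])
        report = evaluate_recovery(self.truth(), selected_pairs=selected)
        assert report.pair_recall == 0.0 and report.pair_fdr == 0.0

    def test_perfect_clustering_ari_one(self):
        report = evaluate_recovery(self.truth(), recovered_clusters=[{"p0"}, {"p1"}])
        assert report.ari == pytest.approx(1.0)
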