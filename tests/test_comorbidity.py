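import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from phenominer.comorbidity import (
    bh_select,
    comorbidity_score,
    fisher_enrichment_p,
    heatmap_order,
    pair_count,
    rank_all_pairs,
)
from phenominer.matrix import build_matrix


def hypergeom_tail_bruteforce(obs, n_a, n_b, n_total):
    """Exhaustive hypergeometric upper tail via binomial coefficients."""
    denom = math.comb(n_total, n_b)
    total = 0
    for k in range(obs, min(n_a, n_b) + 1):
        total += math.comb(n_a, k) * math.comb(n_total - n_a, n_b - k)
    return total / denom


class TestPairCount:
    @pytest.mark.parametrize("n,expected", [(674, 226801), (0, 0), (3, 3), (2, 1)])
    def test_examples(self, n, expected):
        assert pair_count(n) == expected


class TestFisher:
    def test_zero_overlap_p_one(self):
        assert fisher_enrichment_p(0, 5, 7, 50) == 1.0

    def test_full_overlap_small(self):
        assert fisher_enrichment_p(5, 5, 5, 10) == pytest.approx(1 / 252, rel=1e-12)

    def test_partial_overlap_small(self):
        assert fisher_enrichment_p(1, 2, 2, 4) == pytest.approx(5 / 6, rel=1e-12)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment_p(6, 5, 7, 50)
        with pytest.raises(ValueError):
            fisher_enrichment_p(0, 30, 30, 50)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n_total = int(rng.integers(2, 61))
            n_a = int(rng.integers(0, n_total + 1))
            n_b = int(rng.integers(0, n_total + 1))
            lo = max(0, n_a + n_b - n_total)
            obs = int(rng.integers(lo, min(n_a, n_b) + 1))
            expected = hypergeom_tail_bruteforce(obs, n_a, n_b, n_total)
            assert fisher_enrichment_p(obs, n_a, n_b, n_total) == pytest.approx(
                expected, abs=1e-12
            )

    def test_matches_scipy_fisher_exact(self):
        for obs, n_a, n_b, n_total in [(8, 20, 15, 100), (3, 5, 40, 60), (2, 2, 2, 10)]:
            table = [
                [obs, n_a - obs],
                [n_b - obs, n_total - n_a - n_b + obs],
            ]
            _, p = fisher_exact(table, alternative="greater")
            assert fisher_enrichment_p(obs, n_a, n_b, n_total) == pytest.approx(p, rel=1e-9)


class TestScore:
    def test_absent_codes_score_zero(self):
        assert comorbidity_score(0, 0, 0, 100) == 0.0

    def test_direct_evaluation(self):
        assert comorbidity_score(3, 10, 20, 100) == pytest.approx(math.log2(4 / 3))

    def test_cutoff_value_at_twofold(self):
        # obs=3 with expt=1 lands exactly on the two-fold cutoff
        assert comorbidity_score(3, 10, 10, 100) == pytest.approx(1.0)

    def test_symmetric(self):
        assert comorbidity_score(4, 12, 30, 200) == comorbidity_score(4, 30, 12, 200)

    def test_zero_population_rejected(self):
        with pytest.raises(ValueError):
            comorbidity_score(0, 0, 0, 0)


class TestBhSelect:
    def frame(self, ps, scores=None):
        n = len(ps)
        return pd.DataFrame(
            {
                "code_a": [f"A{i:02d}" for i in range(n)],
                "code_b": [f"B{i:02d}" for i in range(n)],
                "n_a": 10,
                "n_b": 10,
                "obs": 5,
                "expt": 1.0,
                "score": scores if scores is not None else [2.0] * n,
                "p": ps,
            }
        )

    def test_hand_worked_correction(self):
        out = bh_select(self.frame([0.001, 0.008, 0.04]), q=0.01).sort_values("rank")
        assert list(out["corrected_p"]) == pytest.approx([0.003, 0.012, 0.04])
        assert list(out.sort_values("rank")["selected"]) == [True, False, False]

    def test_all_null_nothing_selected(self):
        out = bh_select(self.frame([1.0, 1.0, 1.0]))
        assert not out["selected"].any()

    def test_single_significant_pair(self):
        out = bh_select(self.frame([0.005]))
        assert out["selected"].all()

    def test_score_cutoff_vetoes_significant_pair(self):
        out = bh_select(self.frame([1e-6, 1e-6], scores=[2.0, 0.5]))
        assert out.set_index("score")["selected"].to_dict() == {2.0: True, 0.5: False}

    def test_empty_input(self):
        out = bh_select(self.frame([]).iloc[:0])
        assert out.empty and "selected" in out.columns

    def test_matches_statsmodels_bh(self):
        rng = np.random.default_rng(3)
        ps = np.concatenate([rng.uniform(0, 1e-4, 15), rng.uniform(0, 1, 200)])
        out = bh_select(self.frame(list(ps)), q=0.01).sort_values("rank")
        reject, adj, *_ = multipletests(sorted(ps), alpha=0.01, method="fdr_bh")
        assert np.clip(out["corrected_p"].to_numpy(), 0, 1) == pytest.approx(adj)
        assert list(out["selected"]) == list(reject)


class TestRankAllPairs:
    def test_three_codes_three_pairs(self):
        m = build_matrix([("p1", "F20"), ("p1", "E10"), ("p2", "R50")])
        assert len(rank_all_pairs(m)) == 3

    def test_planted_cooccurrence_ranks_first(self):
        rng = np.random.default_rng(1)
        rows = []
        for i in range(400):
            pid = f"p{i}"
            if i < 12:  # rare, perfectly co-occurring pair
                rows += [(pid, "A01"), (pid, "B02")]
            for code in ("C10", "C11", "C12", "C13"):
                if rng.random() < 0.3:
                    rows.append((pid, code))
        ranked = rank_all_pairs(build_matrix(rows)).sort_values("p")
        top = ranked.iloc[0]
        assert {top["code_a"], top["code_b"]} == {"A01", "B02"}

    def test_patient_order_invariance(self, small_cohort):
        rows = list(small_cohort["assigned"])
        a = rank_all_pairs(build_matrix(rows))
        b = rank_all_pairs(build_matrix(list(reversed(rows))))
        pd.testing.assert_frame_equal(a, b)

    def test_symmetry_by_construction(self, small_cohort):
        ranked = rank_all_pairs(build_matrix(small_cohort["assigned"]))
        assert (ranked["code_a"] < ranked["code_b"]).all()  # each unordered pair once


class TestHeatmapOrder:
    def test_two_codes(self):
        pairs = bh_select(
            pd.DataFrame(
                {
                    "code_a": ["A01"],
                    "code_b": ["B02"],
                    "n_a": [10],
                    "n_b": [10],
                    "obs": [8],
                    "expt": [1.0],
                    "score": [2.0],
                    "p": [1e-8],
                }
            )
        )
        order, mat = heatmap_order(pairs, top_k=2)
        assert set(order) == {"A01", "B02"} and mat.shape == (2, 2)

    def test_blocks_stay_contiguous(self):
        codes_x = ["X00", "X01", "X02"]
        codes_y = ["Y00", "Y01", "Y02"]
        rows = []
        for a, b, s in [
            *[(a, b, 3.0) for i, a in enumerate(codes_x) for b in codes_x[i + 1 :]],
            *[(a, b, 3.0) for i, a in enumerate(codes_y) for b in codes_y[i + 1 :]],
            *[(a, b, 0.2) for a in codes_x for b in codes_y],
        ]:
            rows.append(
                {
                    "code_a": a,
                    "code_b": b,
                    "n_a": 10,
                    "n_b": 10,
                    "obs": 5,
                    "expt": 1.0,
                    "score": s,
                    "p": 1e-9,
                    "selected": True,
                }
            )
        order, _ = heatmap_order(pd.DataFrame(rows), top_k=6)
        x_pos = sorted(order.index(c) for c in codes_x)
        assert x_pos in ([0, 1, 2], [3, 4, 5])

    def test_top_k_zero(self):
        order, mat = heatmap_order(pd.DataFrame(), top_k=0)
        assert order == [] and mat.empty

    def test_top_k_clamped_with_warning(self):
        pairs = pd.DataFrame(
            {
                "code_a": ["A01"],
                "code_b": ["B02"],
                "n_a": [5],
                "n_b": [5],
                "obs": [4],
                "expt": [0.5],
                "score": [1.5],
                "p": [1e-5],
                "selected": [True],
            }
        )
        with pytest.warns(UserWarning):
            order, _ = heatmap_order(pairs, top_k=10)
        assert set(order) == {"A01", "B02"}
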