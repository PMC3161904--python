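import numpy as np
import pytest
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster

from phenominer.matrix import AssociationMatrix, build_matrix
from phenominer.stratification import (
    average_linkage,
    build_patient_network,
    cluster_profile,
    cut_and_select,
    filter_patients,
    patient_distance,
    stratify,
)


def matrix_from_counts(counts, patients=None, codes=None):
    counts = np.asarray(counts)
    patients = patients or [f"p{i}" for i in range(counts.shape[0])]
    codes = codes or [f"A{j:02d}" for j in range(counts.shape[1])]
    prov = (counts > 0).astype(np.int8)
    return AssociationMatrix(
        patients=patients, codes=codes, counts=sp.csr_matrix(counts), provenance=sp.csr_matrix(prov)
    )


def bruteforce_upgma_heights(dist):
    """O(n^3) UPGMA: repeatedly merge the closest cluster pair at mean distance."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return heights


class TestFilterPatients:
    def test_too_few_codes_dropped(self):
        m = matrix_from_counts([[1, 1, 0], [1, 1, 1]])
        sub = filter_patients(m, min_codes=3)
        assert sub.patients == ["p1"]

    def test_exclusion_applies_before_min_codes(self):
        m = matrix_from_counts([[1, 1, 1]], codes=["A00", "A01", "R52"])
        sub = filter_patients(m, min_codes=3, excluded_codes=("R52",))
        assert sub.patients == []

    def test_identity_when_nothing_to_drop(self):
        m = matrix_from_counts([[1, 1, 1], [2, 1, 3]])
        sub = filter_patients(m, min_codes=3)
        assert sub.patients == m.patients and sub.codes == m.codes


class TestPatientDistance:
    def test_identical_patients(self):
        m = matrix_from_counts([[2, 1, 0], [2, 1, 0], [0, 1, 1]])
        d = patient_distance(m)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports(self):
        m = matrix_from_counts([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]])
        assert patient_distance(m)[0, 1] == pytest.approx(1.0)

    def test_half_overlap(self):
        # equal df everywhere so idf scales cancel in the cosine
        m = matrix_from_counts([[1, 1, 0], [1, 0, 1], [0, 1, 1]])
        assert patient_distance(m)[0, 1] == pytest.approx(0.5)

    def test_zero_vector_rejected(self):
        # a code present in every patient has idf 0 -> zero TF-IDF vector
        m = matrix_from_counts([[1], [1]])
        with pytest.raises(ValueError):
            patient_distance(m)


class TestAverageLinkage:
    def test_two_points(self):
        z = average_linkage(np.array([[0.0, 0.3], [0.3, 0.0]]))
        assert z.shape == (1, 4) and z[0, 2] == pytest.approx(0.3)

    def test_three_points_upgma_arithmetic(self):
        d = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.9], [0.9, 0.9, 0.0]])
        z = average_linkage(d)
        assert list(z[:, 2]) == pytest.approx([0.1, 0.9])

    def test_matches_bruteforce_upgma(self):
        rng = np.random.default_rng(5)
        for n in (4, 6, 8):
            for _ in range(10):
                x = rng.random((n, 3))
                dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
                z = average_linkage(dist)
                assert list(z[:, 2]) == pytest.approx(bruteforce_upgma_heights(dist), abs=1e-12)


class TestCutAndSelect:
    def test_all_far_apart_gives_singletons(self):
        d = np.full((5, 5), 0.9)
        np.fill_diagonal(d, 0.0)
        labels, kept = cut_and_select(average_linkage(d), 5, cs_threshold=0.6, min_size=25)
        assert len(np.unique(labels)) == 5 and kept == []

    def test_planted_block_selected(self):
        n = 30
        d = np.full((n + 2, n + 2), 0.9)
        d[:n, :n] = 0.05
        np.fill_diagonal(d, 0.0)
        _, kept = cut_and_select(average_linkage(d), n + 2, cs_threshold=0.6, min_size=25)
        assert len(kept) == 1 and len(kept[0]) == n

    def test_min_size_one_returns_all(self):
        d = np.full((4, 4), 0.9)
        np.fill_diagonal(d, 0.0)
        _, kept = cut_and_select(average_linkage(d), 4, cs_threshold=0.6, min_size=1)
        assert sum(len(c) for c in kept) == 4

    def test_cuts_are_nested(self):
        rng = np.random.default_rng(11)
        x = rng.random((20, 4))
        dist = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
        z = average_linkage(dist)
        fine = fcluster(z, t=0.2, criterion="distance")
        coarse = fcluster(z, t=0.6, criterion="distance")
        # each fine cluster maps into exactly one coarse cluster
        for lab in np.unique(fine):
            assert len(np.unique(coarse[fine == lab])) == 1


class TestClusterProfile:
    def test_single_shared_code(self):
        m = matrix_from_counts([[3, 0], [1, 0], [0, 2]])
        profile, top = cluster_profile(m, {"p0", "p1"})
        assert profile["A00"] == pytest.approx(1.0)
        assert top == "A00"

    def test_equal_weights_split_half(self):
        m = matrix_from_counts([[1, 1, 0], [1, 1, 0], [0, 0, 1]])
        profile, top = cluster_profile(m, {"p0", "p1"})
        assert profile["A00"] == pytest.approx(0.5)
        assert profile["A01"] == pytest.approx(0.5)
        assert top == "A00"  # lexicographic tie-break

    def test_empty_cluster_rejected(self):
        m = matrix_from_counts([[1]])
        with pytest.raises(ValueError):
            cluster_profile(m, set())

    def test_unknown_member_rejected(self):
        m = matrix_from_counts([[1]])
        with pytest.raises(ValueError):
            cluster_profile(m, {"ghost"})


class TestPatientNetwork:
    def test_no_qualifying_edges(self):
        sims = np.array([[1.0, 0.2], [0.2, 1.0]])
        g = build_patient_network(sims, ["p0", "p1"], [{0, 1}], cs_threshold=0.6)
        assert g.number_of_edges() == 0

    def test_clique_of_near_identicals(self):
        sims = np.full((4, 4), 0.95)
        np.fill_diagonal(sims, 1.0)
        g = build_patient_network(sims, [f"p{i}" for i in range(4)], [{0, 1, 2, 3}])
        assert g.number_of_edges() == 6

    def test_two_separated_clusters_two_components(self):
        import networkx as nx

        sims = np.full((6, 6), 0.1)
        sims[:3, :3] = 0.9
        sims[3:, 3:] = 0.9
        np.fill_diagonal(sims, 1.0)
        g = build_patient_network(sims, [f"p{i}" for i in range(6)], [{0, 1, 2}, {3, 4, 5}])
        assert nx.number_connected_components(g) == 2


class TestStratify:
    def test_end_to_end_recovers_planted_block(self):
        counts = np.zeros((40, 8), dtype=int)
        counts[:30, :4] = 2  # tight block sharing four codes
        rng = np.random.default_rng(2)
        counts[30:, 4:] = rng.integers(1, 3, size=(10, 4))
        counts[30:, 0] = [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]
        m = matrix_from_counts(counts)
        result = stratify(m, min_codes=3, min_size=25)
        assert len(result.clusters) == 1
        assert {f"p{i}" for i in range(30)} <= result.clusters[0]
        assert result.top_codes[0] in {"A00", "A01", "A02", "A03"}
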