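"""Patient stratification by TF-IDF code-vector similarity.

Patients with at least three distinct level-3 codes (after removing
configurable trivial/symptom codes) are compared by cosine similarity (CS)
of their TF-IDF code vectors; 1−CS is the distance for average-linkage
(UPGMA) hierarchical clustering.  The tree is cut at CS = 0.6 and clusters
with ≥ 25 members are kept.  Each kept cluster is profiled by pooling its
members' counts into one document and re-weighting with the patient-level
idf, reporting each code's fraction of the pooled TF-IDF vector and the top
code.  A patient network links members of kept clusters whose pairwise CS
exceeds the cut threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics.pairwise import cosine_similarity as _sk_cosine

from .matrix import AssociationMatrix

__all__ = [
    "ClusterResult",
    "filter_patients",
    "patient_distance",
    "average_linkage",
    "cut_and_select",
    "cluster_profile",
    "build_patient_network",
    "stratify",
]


def filter_patients(
    matrix: AssociationMatrix,
    min_codes: int = 3,
    excluded_codes: tuple[str, ...] = (),
) -> AssociationMatrix:
    """Drop excluded code columns, then patients with < min_codes codes left.

    min_codes counts distinct level-3 codes after the exclusion, so a
    patient can be lost to the exclusion list even with min_codes codes in
    the raw matrix.
    """
    excluded = set(excluded_codes)
    keep_cols = np.array([j for j, c in enumerate(matrix.codes) if c not in excluded], dtype=int)
    sub = matrix.binary[:, keep_cols] if len(keep_cols) else matrix.binary[:, :0]
    distinct = np.asarray(sub.sum(axis=1)).ravel()
    keep_rows = np.where(distinct >= min_codes)[0]
    return matrix.subset(keep_rows, keep_cols)


def patient_distance(submatrix: AssociationMatrix) -> np.ndarray:
    """Symmetric 1−CS distance matrix over TF-IDF patient vectors."""
    tfidf = submatrix.tfidf
    row_norms = np.sqrt(np.asarray(tfidf.multiply(tfidf).sum(axis=1)).ravel())
    if np.any(row_norms == 0):
        bad = [submatrix.patients[i] for i in np.where(row_norms == 0)[0]]
        raise ValueError(f"zero TF-IDF vector for patients {bad}; filter first")
    cs = _sk_cosine(tfidf)
    dist = 1.0 - np.clip(cs, 0.0, 1.0)
    np.fill_diagonal(dist, 0.0)
    return dist


def average_linkage(dist: np.ndarray) -> np.ndarray:
    """UPGMA merge tree (scipy linkage encoding) for a distance matrix."""
    n = dist.shape[0]
    if n < 2:
        return np.empty((0, 4))
    return linkage(squareform(dist, checks=False), method="average")


def cut_and_select(
    dendrogram: np.ndarray,
    n_leaves: int,
    cs_threshold: float = 0.6,
    min_size: int = 25,
) -> tuple[np.ndarray, list[set[int]]]:
    """Cut the tree at distance 1−cs_threshold; keep clusters ≥ min_size.

    Returns (labels over all leaves, list of kept clusters as leaf-index
    sets).  Labels follow scipy's flat-cluster numbering.
    """
    if n_leaves == 0:
        return np.array([], dtype=int), []
    if len(dendrogram) == 0:
        labels = np.ones(n_leaves, dtype=int)
    else:
        labels = fcluster(dendrogram, t=1.0 - cs_threshold, criterion="distance")
    kept = []
    for lab in np.unique(labels):
        members = set(np.where(labels == lab)[0].tolist())
        if len(members) >= min_size:
            kept.append(members)
    kept.sort(key=lambda s: (-len(s), min(s)))
    return labels, kept


def cluster_profile(
    matrix: AssociationMatrix, cluster: set[str] | list[str]
) -> tuple[pd.Series, str]:
    """Pooled TF-IDF profile of one cluster.

    Member counts are summed into a single document, re-weighted with the
    patient-level idf (df and N from ``matrix``) so profiles are comparable
    across clusters, and normalized to fractions of the pooled vector.
    Returns (code → fraction, top code); ties on the top code break
    lexicographically.
    """
    members = sorted(set(cluster))
    if not members:
        raise ValueError("empty cluster")
    p_idx = {p: i for i, p in enumerate(matrix.patients)}
    missing = [m for m in members if m not in p_idx]
    if missing:
        raise ValueError(f"cluster members not in matrix: {missing}")
    rows = np.array([p_idx[m] for m in members], dtype=int)
    pooled_tf = np.asarray(matrix.counts[rows].sum(axis=0)).ravel().astype(float)
    df = matrix.df
    idf = np.zeros_like(pooled_tf)
    nz = df > 0
    idf[nz] = np.log(matrix.n_patients / df[nz])
    weights = pooled_tf * idf
    total = weights.sum()
    fractions = weights / total if total > 0 else weights
    profile = pd.Series(fractions, index=matrix.codes)
    top = profile.index[np.lexsort((profile.index, -profile.to_numpy()))[0]]
    return profile, str(top)


def build_patient_network(
    similarities: np.ndarray,
    patients: list[str],
    clusters: list[set[int]],
    cs_threshold: float = 0.6,
) -> nx.Graph:
    """Network of kept-cluster members with CS > threshold edges.

    Nodes are members of the kept clusters that have at least one
    qualifying edge; the node attribute ``cluster`` records membership.
    """
    g = nx.Graph()
    member_cluster: dict[int, int] = {}
    for cid, members in enumerate(clusters):
        for i in members:
            member_cluster[i] = cid
    members = sorted(member_cluster)
    for a_pos, i in enumerate(members):
        for j in members[a_pos + 1 :]:
            cs = float(similarities[i, j])
            if cs > cs_threshold:
                for node in (i, j):
                    if node not in g:
                        g.add_node(patients[node], cluster=member_cluster[node])
                g.add_edge(patients[i], patients[j], similarity=cs)
    return g


@dataclass
class ClusterResult:
    included_patients: list[str]
    dendrogram: np.ndarray
    labels: np.ndarray
    clusters: list[set[str]]
    cluster_profiles: list[pd.Series] = field(default_factory=list)
    top_codes: list[str] = field(default_factory=list)
    network: nx.Graph | None = None

    def membership_frame(self) -> pd.DataFrame:
        rows = [
            {"patient": p, "cluster": cid}
            for cid, members in enumerate(self.clusters)
            for p in sorted(members)
        ]
        return pd.DataFrame(rows, columns=["patient", "cluster"])


def stratify(
    matrix: AssociationMatrix,
    min_codes: int = 3,
    excluded_codes: tuple[str, ...] = (),
    cs_threshold: float = 0.6,
    min_size: int = 25,
) -> ClusterResult:
    """Full stratification pass: filter, cluster, cut, profile, network."""
    sub = filter_patients(matrix, min_codes=min_codes, excluded_codes=excluded_codes)
    if sub.n_patients == 0:
        return ClusterResult([], np.empty((0, 4)), np.array([], dtype=int), [])
    dist = patient_distance(sub)
    dendro = average_linkage(dist)
    labels, kept_idx = cut_and_select(dendro, sub.n_patients, cs_threshold, min_size)
    clusters = [{sub.patients[i] for i in members} for members in kept_idx]
    profiles, tops = [], []
    for members in clusters:
        profile, top = cluster_profile(sub, members)
        profiles.append(profile)
        tops.append(top)
    network = build_patient_network(1.0 - dist, sub.patients, kept_idx, cs_threshold)
    return ClusterResult(
        included_patients=list(sub.patients),
        dendrogram=dendro,
        labels=labels,
        clusters=clusters,
        cluster_profiles=profiles,
        top_codes=tops,
        network=network,
    )
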