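"""Comorbidity ranking of ICD10 code pairs.

Every unordered pair of level-3 codes is tested for over-co-occurrence in
the patient cohort.  For a pair (A, B) with n_A and n_B affected patients,
Obs co-affected out of N, the one-sided Fisher exact (hypergeometric upper
tail) p-value measures significance and the comorbidity score

    score = log2((Obs + 1) / (Expt + 1)),   Expt = n_A·n_B / N

measures effect size; the pseudo-count damps the low-prevalence advantage
and a score cutoff of 1.0 keeps pairs co-occurring (approximately) more
than twice as often as expected.  Selection applies Benjamini–Hochberg:
p-values are sorted, corrected as p·m/rank (m = all pairs), made monotone
by the step-up rule, and kept while the corrected value stays below q.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom

from .matrix import AssociationMatrix

__all__ = [
    "pair_count",
    "fisher_enrichment_p",
    "comorbidity_score",
    "rank_all_pairs",
    "bh_select",
    "heatmap_order",
]


def pair_count(n_codes: int) -> int:
    """Number of unordered pairs of n codes: (n²−n)/2."""
    if n_codes < 0:
        raise ValueError("n_codes must be nonnegative")
    return (n_codes * n_codes - n_codes) // 2


def _check_counts(obs: int, n_a: int, n_b: int, n_total: int) -> None:
    if min(obs, n_a, n_b) < 0 or n_total <= 0:
        raise ValueError("counts must be nonnegative with n_total > 0")
    if obs > min(n_a, n_b) or max(n_a, n_b) > n_total or n_a + n_b - obs > n_total:
        raise ValueError(
            f"inconsistent 2x2 counts: obs={obs}, n_a={n_a}, n_b={n_b}, n_total={n_total}"
        )


def fisher_enrichment_p(obs: int, n_a: int, n_b: int, n_total: int) -> float:
    """One-sided enrichment p: P(X ≥ obs), X ~ Hypergeom(n_total, n_a, n_b).

    Equals Fisher's exact test with alternative 'greater' on the 2×2 table
    (A&B, A¬B, B¬A, ¬A¬B).
    """
    _check_counts(obs, n_a, n_b, n_total)
    return float(hypergeom.sf(obs - 1, n_total, n_a, n_b))


def comorbidity_score(obs: int, n_a: int, n_b: int, n_total: int) -> float:
    """log2((obs+1)/(expt+1)) with expt = n_a·n_b/n_total."""
    _check_counts(obs, n_a, n_b, n_total)
    expt = n_a * n_b / n_total
    return float(np.log2((obs + 1) / (expt + 1)))


def rank_all_pairs(matrix: AssociationMatrix) -> pd.DataFrame:
    """Score and test every unordered code pair of the matrix.

    Returns one row per pair with columns code_a, code_b, n_a, n_b, obs,
    expt, score, p — vectorised over the (possibly large) pair set.  Ties in
    p are broken lexicographically on (code_a, code_b) when ranked later.
    """
    if len(matrix.codes) < 2:
        raise ValueError("need at least two codes to rank pairs")
    binary = matrix.binary.astype(np.int64)
    n_total = matrix.n_patients
    overlap = (binary.T @ binary).toarray()
    n_per_code = np.asarray(binary.sum(axis=0)).ravel()
    iu, ju = np.triu_indices(len(matrix.codes), k=1)
    n_a = n_per_code[iu]
    n_b = n_per_code[ju]
    obs = overlap[iu, ju]
    expt = n_a * n_b / n_total
    score = np.log2((obs + 1) / (expt + 1))
    p = hypergeom.sf(obs - 1, n_total, n_a, n_b)
    codes = np.asarray(matrix.codes)
    return pd.DataFrame(
        {
            "code_a": codes[iu],
            "code_b": codes[ju],
            "n_a": n_a,
            "n_b": n_b,
            "obs": obs,
            "expt": expt,
            "score": score,
            "p": np.clip(p, 0.0, 1.0),
        }
    )


def bh_select(
    pairs: pd.DataFrame,
    q: float = 0.01,
    score_cutoff: float = 1.0,
    m: int | None = None,
) -> pd.DataFrame:
    """Apply the BH step-up selection to ranked pairs.

    ``m`` defaults to the total number of pairs handed in (the full pair
    universe, including pairs the score cutoff later removes).  Adds columns
    rank, corrected_p (p·m/rank, step-up monotone) and selected
    (corrected_p < q AND score ≥ score_cutoff).  The result is sorted by
    score, descending, for reporting.
    """
    if pairs.empty:
        out = pairs.copy()
        out["rank"] = pd.Series(dtype=int)
        out["corrected_p"] = pd.Series(dtype=float)
        out["selected"] = pd.Series(dtype=bool)
        return out
    if m is None:
        m = len(pairs)
    df = pairs.sort_values(["p", "code_a", "code_b"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    raw = df["p"].to_numpy() * m / df["rank"].to_numpy()
    # step-up monotonicity: adjusted p is the running minimum from the bottom
    corrected = np.minimum.accumulate(raw[::-1])[::-1]
    df["corrected_p"] = corrected
    df["selected"] = (corrected < q) & (df["score"] >= score_cutoff)
    return df.sort_values(["score", "code_a", "code_b"], ascending=[False, True, True]).reset_index(
        drop=True
    )


def heatmap_order(
    pairs: pd.DataFrame, top_k: int
) -> tuple[list[str], pd.DataFrame]:
    """Leaf order and score matrix for the comorbidity heatmap.

    Takes the selected pairs sorted by score (descending) and collects codes
    until ``top_k`` distinct codes are reached (clamped, with a warning, to
    the codes available).  Codes are clustered by average linkage on
    distance = max_score − score (0 on the diagonal); returns the dendrogram
    leaf order and the symmetric score matrix.
    """
    if top_k <= 0:
        return [], pd.DataFrame()
    sel = pairs[pairs.get("selected", pd.Series(True, index=pairs.index))].sort_values(
        ["score", "code_a", "code_b"], ascending=[False, True, True]
    )
    ordered_codes: list[str] = []
    for row in sel.itertuples(index=False):
        for c in (row.code_a, row.code_b):
            if c not in ordered_codes:
                ordered_codes.append(c)
        if len(ordered_codes) >= top_k:
            break
    if len(ordered_codes) < top_k:
        import warnings

        warnings.warn(
            f"only {len(ordered_codes)} codes available for top_k={top_k}", stacklevel=2
        )
    codes = sorted(ordered_codes[:top_k])
    idx = {c: i for i, c in enumerate(codes)}
    score_mat = np.zeros((len(codes), len(codes)))
    relevant = pairs[pairs["code_a"].isin(idx) & pairs["code_b"].isin(idx)]
    for row in relevant.itertuples(index=False):
        i, j = idx[row.code_a], idx[row.code_b]
        score_mat[i, j] = score_mat[j, i] = row.score
    frame = pd.DataFrame(score_mat, index=codes, columns=codes)
    if len(codes) < 2:
        return codes, frame
    dist = score_mat.max() - score_mat
    np.fill_diagonal(dist, 0.0)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    leaf_codes = [codes[i] for i in order]
    return leaf_codes, frame.loc[leaf_codes, leaf_codes]
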