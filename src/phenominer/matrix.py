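"""Patient × ICD10 association matrix.

Assigned (structured-field) codes and accepted mined hits are merged into a
sparse count matrix whose rows describe the morbidity of a patient as a
vector in ICD10 space and whose columns describe the prevalence of a code
in patient space.  Three views exist: raw incidence counts, binary
presence/absence, and TF-IDF weights tf·ln(N/df) where tf is the cell count,
df the number of patients carrying the code and N the cohort size.  Every
nonzero cell carries provenance: assigned, mined or both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .icd10 import is_level3
from .mining import ACCEPTED, MiningHit

__all__ = ["AssociationMatrix", "build_matrix", "tfidf_weight", "cosine_similarity"]

PROVENANCE = {1: "assigned", 2: "mined", 3: "both"}
_PROV_CODE = {v: k for k, v in PROVENANCE.items()}


def tfidf_weight(tf: float, df: int, n_patients: int) -> float:
    """TF-IDF weight tf·ln(N/df).

    Rewards a code frequent in the individual record and penalizes codes
    prevalent across the whole cohort (df = N gives weight 0).
    """
    if tf == 0:
        return 0.0
    if df <= 0 or df > n_patients:
        raise ValueError(f"inconsistent df={df} for n_patients={n_patients} with tf>0")
    return float(tf) * float(np.log(n_patients / df))


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of the angle between two nonnegative vectors, in [0, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class AssociationMatrix:
    patients: list[str]
    codes: list[str]
    counts: sp.csr_matrix  # incidences per cell
    provenance: sp.csr_matrix  # 1 assigned, 2 mined, 3 both
    _tfidf: sp.csr_matrix | None = field(default=None, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.patients), len(self.codes))

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def binary(self) -> sp.csr_matrix:
        b = (self.counts > 0).astype(np.int8)
        b.eliminate_zeros()
        return b.tocsr()

    @property
    def df(self) -> np.ndarray:
        """Documents-with-code per column (binary column sums)."""
        return np.asarray(self.binary.sum(axis=0)).ravel().astype(int)

    @property
    def tfidf(self) -> sp.csr_matrix:
        if self._tfidf is None:
            n = self.n_patients
            df = self.df
            idf = np.zeros(len(self.codes))
            nz = df > 0
            idf[nz] = np.log(n / df[nz])
            self._tfidf = self.counts.multiply(sp.csr_matrix(idf)).tocsr()
        return self._tfidf

    def provenance_of(self, patient: str, code: str) -> str:
        i = self.patients.index(patient)
        j = self.codes.index(code)
        v = int(self.provenance[i, j])
        if v == 0:
            raise KeyError(f"cell ({patient}, {code}) is empty")
        return PROVENANCE[v]

    # --- persistence -----------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "counts.mtx"), self.counts.tocoo())
        (directory / "patients.txt").write_text("\n".join(self.patients) + "\n")
        (directory / "codes.txt").write_text("\n".join(self.codes) + "\n")
        self.to_long().to_csv(directory / "matrix_long.tsv", sep="\t", index=False)

    def to_long(self) -> pd.DataFrame:
        coo = self.counts.tocoo()
        tfidf = self.tfidf
        rows = []
        for i, j, c in zip(coo.row, coo.col, coo.data):
            rows.append(
                {
                    "patient": self.patients[i],
                    "code": self.codes[j],
                    "count": int(c),
                    "provenance": PROVENANCE[int(self.provenance[i, j])],
                    "tfidf": float(tfidf[i, j]),
                }
            )
        return pd.DataFrame(rows, columns=["patient", "code", "count", "provenance", "tfidf"])

    @classmethod
    def load(cls, directory: str | Path) -> "AssociationMatrix":
        directory = Path(directory)
        counts = sp.csr_matrix(mmread(str(directory / "counts.mtx")))
        patients = (directory / "patients.txt").read_text().splitlines()
        codes = (directory / "codes.txt").read_text().splitlines()
        long = pd.read_csv(directory / "matrix_long.tsv", sep="\t")
        p_idx = {p: i for i, p in enumerate(patients)}
        c_idx = {c: j for j, c in enumerate(codes)}
        prov = sp.dok_matrix(counts.shape, dtype=np.int8)
        for row in long.itertuples(index=False):
            prov[p_idx[str(row.patient)], c_idx[row.code]] = _PROV_CODE[row.provenance]
        return cls(patients=patients, codes=codes, counts=counts, provenance=prov.tocsr())

    def subset(self, patient_idx: np.ndarray, code_idx: np.ndarray) -> "AssociationMatrix":
        return AssociationMatrix(
            patients=[self.patients[i] for i in patient_idx],
            codes=[self.codes[j] for j in code_idx],
            counts=self.counts[patient_idx][:, code_idx].tocsr(),
            provenance=self.provenance[patient_idx][:, code_idx].tocsr(),
        )


def build_matrix(
    assigned: Iterable[tuple[str, str]],
    hits: Sequence[MiningHit] = (),
) -> AssociationMatrix:
    """Merge assigned codes and accepted mined hits into the matrix.

    Repeated identical assignments of one code to one patient count once
    (structured records are de-duplicated); every accepted mined incidence
    counts.  All codes must be level-3; hits must all be accepted.
    """
    assigned_set: set[tuple[str, str]] = set()
    for patient, code in assigned:
        if not is_level3(code):
            raise ValueError(f"assigned code {code!r} is not level-3")
        assigned_set.add((str(patient), code))
    mined_counts: dict[tuple[str, str], int] = {}
    for h in hits:
        if h.status != ACCEPTED:
            raise ValueError("build_matrix expects accepted hits only")
        if not is_level3(h.code):
            raise ValueError(f"mined code {h.code!r} is not level-3")
        key = (h.patient_id, h.code)
        mined_counts[key] = mined_counts.get(key, 0) + 1

    cells = set(assigned_set) | set(mined_counts)
    patients = sorted({p for p, _ in cells})
    codes = sorted({c for _, c in cells})
    p_idx = {p: i for i, p in enumerate(patients)}
    c_idx = {c: j for j, c in enumerate(codes)}
    counts = sp.dok_matrix((len(patients), len(codes)), dtype=np.int64)
    prov = sp.dok_matrix((len(patients), len(codes)), dtype=np.int8)
    for p, c in cells:
        i, j = p_idx[p], c_idx[c]
        n = (1 if (p, c) in assigned_set else 0) + mined_counts.get((p, c), 0)
        counts[i, j] = n
        prov[i, j] = (1 if (p, c) in assigned_set else 0) | (2 if (p, c) in mined_counts else 0)
    return AssociationMatrix(
        patients=patients, codes=codes, counts=counts.tocsr(), provenance=prov.tocsr()
    )
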