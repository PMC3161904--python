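"""ICD10 chapter-level comorbidity network.

For each of the 22 chapters a binary patient-space vector marks which
patients carry at least one code from the chapter.  Pairwise cosine
similarity between these vectors quantifies chapter-level comorbidity
(0 = none, 1 = identical patient sets), and each chapter's frequency is its
share of all patient–chapter associations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .icd10 import CHAPTER_RANGES, chapter_of
from .matrix import AssociationMatrix

__all__ = ["ChapterNetwork", "chapter_vectors", "chapter_similarity"]

CHAPTER_IDS = tuple(roman for roman, _, _ in CHAPTER_RANGES)


def chapter_vectors(matrix: AssociationMatrix) -> pd.DataFrame:
    """Binary patients × 22-chapters presence matrix.

    Entry (p, ch) is 1 iff patient p has at least one code from chapter ch.
    """
    binary = matrix.binary.toarray()
    out = np.zeros((len(matrix.patients), len(CHAPTER_IDS)), dtype=np.int8)
    col_chapter = [chapter_of(c) for c in matrix.codes]
    ch_idx = {ch: k for k, ch in enumerate(CHAPTER_IDS)}
    for j, ch in enumerate(col_chapter):
        out[:, ch_idx[ch]] |= binary[:, j].astype(np.int8)
    return pd.DataFrame(out, index=matrix.patients, columns=list(CHAPTER_IDS))


@dataclass
class ChapterNetwork:
    frequency: pd.Series  # share of all patient–chapter associations
    similarity: pd.DataFrame  # 22×22 symmetric cosine matrix
    empty_chapters: list[str] = field(default_factory=list)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for ch in CHAPTER_IDS:
            g.add_node(ch, frequency=float(self.frequency[ch]))
        for i, a in enumerate(CHAPTER_IDS):
            for b in CHAPTER_IDS[i + 1 :]:
                s = float(self.similarity.loc[a, b])
                if s > 0:
                    g.add_edge(a, b, similarity=s)
        return g

    def save(self, graphml_path: str | Path, tsv_path: str | Path | None = None) -> None:
        nx.write_graphml(self.to_graph(), str(graphml_path))
        if tsv_path is not None:
            self.similarity.to_csv(tsv_path, sep="\t")


def chapter_similarity(vectors: pd.DataFrame) -> ChapterNetwork:
    """Pairwise cosine similarity and frequencies of chapter vectors.

    Empty chapters (no patient) get similarity 0 to everything by convention
    and are flagged; their self-similarity is 0 as well.
    """
    mat = vectors.to_numpy(dtype=float)
    norms = np.linalg.norm(mat, axis=0)
    nonzero = norms > 0
    if not nonzero.any():
        raise ValueError("no chapter has any patient")
    sim = np.zeros((mat.shape[1], mat.shape[1]))
    scaled = mat[:, nonzero] / norms[nonzero]
    sub = scaled.T @ scaled
    idx = np.where(nonzero)[0]
    sim[np.ix_(idx, idx)] = sub
    counts = mat.sum(axis=0)
    freq = counts / counts.sum()
    return ChapterNetwork(
        frequency=pd.Series(freq, index=vectors.columns),
        similarity=pd.DataFrame(sim, index=vectors.columns, columns=vectors.columns),
        empty_chapters=[c for c, nz in zip(vectors.columns, nonzero) if not nz],
    )
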