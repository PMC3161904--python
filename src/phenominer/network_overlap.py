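"""Shared-interactor analysis of disease pairs on a PPI network.

Each disease's seed genes (e.g. OMIM-derived, supplied as a code→gene
table) are grown into a first-order network: the seeds plus their direct
interaction partners.  For a disease pair, candidate genes are the shared
members adjacent to at least one seed of each disease, excluding the seeds
themselves.  A candidate with degree n, of which k partners fall in the
pair's seed union (size K), is scored by the hypergeometric upper tail
P(X ≥ k) with population M = |network| − 1 — the probability of seeing that
many seed contacts among its partners by chance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DiseaseNetwork",
    "load_ppi",
    "load_seed_map",
    "first_order_network",
    "shared_interactors",
    "candidate_score",
    "score_pair",
]

log = logging.getLogger(__name__)


def load_ppi(path: str | Path) -> nx.Graph:
    """Read an undirected edge list TSV (gene_a<TAB>gene_b).

    Self-loops are dropped and duplicate edges collapse.
    """
    g = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first and not first.lower().startswith("gene"):
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            a, b = parts[0], parts[1]
            if a != b:
                g.add_edge(a, b)
    return g


def load_seed_map(path: str | Path) -> dict[str, set[str]]:
    """Read a code→gene TSV into {code: {genes}}."""
    seeds: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first and not first.lower().startswith("code"):
            fh.seek(0)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                seeds.setdefault(parts[0], set()).add(parts[1])
    return seeds


@dataclass(frozen=True)
class DiseaseNetwork:
    code: str
    seeds: frozenset[str]
    members: frozenset[str]  # seeds plus first-order neighbors
    dropped_seeds: frozenset[str] = frozenset()


def first_order_network(ppi: nx.Graph, seeds: set[str], code: str = "") -> DiseaseNetwork:
    """Seeds plus their direct PPI neighbors.

    Seeds absent from the network are dropped with a logged warning; an
    empty usable seed set is an error.
    """
    usable = {s for s in seeds if s in ppi}
    dropped = set(seeds) - usable
    if dropped:
        log.warning("disease %s: %d seed(s) absent from PPI: %s", code, len(dropped), sorted(dropped))
    if not usable:
        raise ValueError(f"disease {code or '?'}: no seed gene present in the PPI network")
    members = set(usable)
    for s in usable:
        members.update(ppi.neighbors(s))
    return DiseaseNetwork(
        code=code, seeds=frozenset(usable), members=frozenset(members), dropped_seeds=frozenset(dropped)
    )


def shared_interactors(net_a: DiseaseNetwork, net_b: DiseaseNetwork, ppi: nx.Graph) -> set[str]:
    """Candidate genes shared by two disease networks.

    Genes in both member sets, excluding seeds of either disease, that are
    adjacent to at least one seed of A and at least one seed of B.
    Symmetric in its two network arguments.
    """
    shared = (net_a.members & net_b.members) - net_a.seeds - net_b.seeds
    out = set()
    for gene in shared:
        partners = set(ppi.neighbors(gene))
        if partners & net_a.seeds and partners & net_b.seeds:
            out.add(gene)
    return out


def candidate_score(ppi: nx.Graph, candidate: str, seed_union: set[str]) -> float:
    """Hypergeometric tail P(X ≥ k) for a candidate's seed contacts.

    Population M = |nodes| − 1 (every possible partner), K = |seed union|,
    draws n = degree(candidate), successes k = partners in the seed union.
    A degree-0 candidate scores 1 with a warning.
    """
    if candidate not in ppi:
        raise ValueError(f"candidate {candidate!r} not in PPI network")
    if candidate in seed_union:
        raise ValueError(f"candidate {candidate!r} is itself a seed")
    degree = ppi.degree(candidate)
    if degree == 0:
        log.warning("candidate %s has no interaction partners; p = 1", candidate)
        return 1.0
    k = len(set(ppi.neighbors(candidate)) & set(seed_union))
    m_pop = ppi.number_of_nodes() - 1
    return float(hypergeom.sf(k - 1, m_pop, len(seed_union), degree))


def score_pair(
    ppi: nx.Graph,
    seeds_a: set[str],
    seeds_b: set[str],
    code_a: str = "A",
    code_b: str = "B",
) -> pd.DataFrame:
    """Shared-interactor candidates of one disease pair, scored.

    Returns columns code_a, code_b, gene, degree, seed_hits, p sorted by p
    ascending (gene name breaks ties).
    """
    net_a = first_order_network(ppi, seeds_a, code_a)
    net_b = first_order_network(ppi, seeds_b, code_b)
    union = set(net_a.seeds | net_b.seeds)
    rows = []
    for gene in sorted(shared_interactors(net_a, net_b, ppi)):
        degree = ppi.degree(gene)
        seed_hits = len(set(ppi.neighbors(gene)) & union)
        rows.append(
            {
                "code_a": code_a,
                "code_b": code_b,
                "gene": gene,
                "degree": degree,
                "seed_hits": seed_hits,
                "p": candidate_score(ppi, gene, union),
            }
        )
    frame = pd.DataFrame(rows, columns=["code_a", "code_b", "gene", "degree", "seed_hits", "p"])
    return frame.sort_values(["p", "gene"]).reset_index(drop=True)
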