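"""Shared fixtures and independent oracles.

The oracles here deliberately re-derive quantities by the most literal
route available (double loops over the modularity equation, exhaustive set
partitions, brute-force pair counting) so they stay independent of the
library code paths they check.
"""

from __future__ import annotations

import itertools
import random

import pytest

from horizonscan.corpus_io import Corpus, PaperRecord
from horizonscan.graph_build import CitationGraph, build_citation_graph


def modularity_bruteforce(graph: CitationGraph, assignment: dict) -> float:
    """Direct double sum over ordered node pairs of the Q equation."""
    nodes = list(graph.nodes)
    und = graph.undirected
    m = graph.m
    deg = {n: und.degree(n) for n in nodes}
    total = 0.0
    for i in nodes:
        for j in nodes:
            a_ij = 1.0 if i != j and und.has_edge(i, j) else 0.0
            if assignment[i] == assignment[j]:
                total += a_ij - deg[i] * deg[j] / (2.0 * m)
    return total / (2.0 * m)


def all_set_partitions(items: list):
    """Every partition of a small item list (Bell(6) = 203)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for k, block in enumerate(smaller):
            yield smaller[:k] + [block + [first]] + smaller[k + 1 :]
        yield smaller + [[first]]


def partition_to_assignment(blocks: list) -> dict:
    return {node: idx for idx, block in enumerate(blocks) for node in block}


def two_triangles_corpus() -> Corpus:
    records = [
        PaperRecord(id="a1", year=2000),
        PaperRecord(id="a2", year=2001, cited_ids=["a1"]),
        PaperRecord(id="a3", year=2002, cited_ids=["a1", "a2"]),
        PaperRecord(id="b1", year=2000),
        PaperRecord(id="b2", year=2001, cited_ids=["b1"]),
        PaperRecord(id="b3", year=2002, cited_ids=["b1", "b2"]),
    ]
    return Corpus(records=records, provenance="two disjoint triangles")


@pytest.fixture
def triangles_graph() -> CitationGraph:
    return build_citation_graph(two_triangles_corpus())


def random_corpus(n: int, seed: int, p_cite: float = 0.15) -> Corpus:
    """A small random corpus with backward citations and some dangling refs."""
    rng = random.Random(seed)
    records = []
    for i in range(n):
        year = 1990 + i // 3
        cited = [f"R{j:03d}" for j in range(i) if rng.random() < p_cite]
        if rng.random() < 0.1:
            cited.append("DANGLING")
        records.append(
            PaperRecord(
                id=f"R{i:03d}",
                title=f"paper {i}",
                abstract="cell immune response",
                year=year,
                cited_ids=cited,
            ).validate()
        )
    return Corpus(records=records, provenance=f"random({n}, seed={seed})")


def complete_graph_corpus(n: int) -> Corpus:
    """A corpus whose citation graph is the complete graph K_n."""
    records = []
    for i in range(n):
        records.append(
            PaperRecord(id=f"K{i}", year=2000 + i, cited_ids=[f"K{j}" for j in range(i)])
        )
    return Corpus(records=records)


def components_bruteforce(graph: CitationGraph) -> list[set]:
    """Connected components by plain union-find on the undirected edges."""
    parent = {n: n for n in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in graph.undirected.edges:
        parent[find(u)] = find(v)
    comps: dict = {}
    for n in graph.nodes:
        comps.setdefault(find(n), set()).add(n)
    return list(comps.values())


def best_partition_exhaustive(graph: CitationGraph) -> tuple[float, dict]:
    """Global modularity optimum by exhaustive search (graphs <= 6 nodes)."""
    best_q, best_assignment = float("-inf"), None
    for blocks in all_set_partitions(sorted(graph.nodes)):
        assignment = partition_to_assignment(blocks)
        q = modularity_bruteforce(graph, assignment)
        if q > best_q:
            best_q, best_assignment = q, assignment
    return best_q, best_assignment
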