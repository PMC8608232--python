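"""Modularity, Louvain, cluster ranking, and sub-clustering.

The modularity implementation is checked against a literal double-loop
evaluation of the Q equation; Louvain is checked against exhaustive
partition search on tiny graphs, against planted ground truth on generated
graphs, and against the networkx implementations as an independent
cross-check.
"""

from __future__ import annotations

import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from horizonscan.clustering import (
    Partition,
    louvain,
    modularity,
    rank_clusters,
    subpartition,
)
from horizonscan.corpus_io import Corpus, PaperRecord
from horizonscan.graph_build import CitationGraph, build_citation_graph
from horizonscan.synthetic_data import GeneratorConfig, generate_corpus

from conftest import (
    best_partition_exhaustive,
    complete_graph_corpus,
    modularity_bruteforce,
    random_corpus,
    two_triangles_corpus,
)


def _ari(partition: Partition, truth: dict) -> float:
    nodes = sorted(partition.assignment)
    return adjusted_rand_score(
        [truth[n] for n in nodes], [str(partition.assignment[n]) for n in nodes]
    )


class TestModularity:
    def test_single_community_is_exactly_zero(self, triangles_graph):
        assignment = dict.fromkeys(triangles_graph.nodes, 0)
        assert modularity(triangles_graph, assignment) == 0.0

    def test_two_disjoint_triangles_by_component_is_half(self, triangles_graph):
        assignment = {n: n[0] for n in triangles_graph.nodes}  # 'a' vs 'b'
        assert modularity(triangles_graph, assignment) == pytest.approx(0.5, abs=1e-15)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_double_loop(self, seed):
        g = build_citation_graph(random_corpus(20 + seed, seed))
        if g.m == 0:
            pytest.skip("degenerate random draw")
        assignment = {n: hash(n) % 4 for n in g.nodes}
        assert modularity(g, assignment) == pytest.approx(
            modularity_bruteforce(g, assignment), abs=1e-12
        )

    def test_matches_networkx_cross_check(self):
        g = build_citation_graph(random_corpus(30, 7))
        assignment = {n: i % 3 for i, n in enumerate(sorted(g.nodes))}
        comms = {}
        for n, c in assignment.items():
            comms.setdefault(c, set()).add(n)
        expected = nx.community.modularity(g.undirected, comms.values())
        assert modularity(g, assignment) == pytest.approx(expected, abs=1e-12)

    def test_edgeless_graph_is_domain_error(self):
        g = build_citation_graph(Corpus(records=[PaperRecord(id="A", year=2000)]))
        with pytest.raises(ValueError):
            modularity(g, {"A": 0})


class TestLouvain:
    def test_two_triangles_recovers_exhaustive_optimum(self, triangles_graph):
        best_q, _ = best_partition_exhaustive(triangles_graph)
        assert best_q == pytest.approx(0.5, abs=1e-15)  # verified over all 203 partitions
        part = louvain(triangles_graph, seed=0)
        assert part.q == pytest.approx(0.5, abs=1e-12)
        assert part.n_communities == 2
        comms = part.communities()
        assert sorted(map(sorted, comms.values())) == [["a1", "a2", "a3"], ["b1", "b2", "b3"]]

    def test_complete_graph_stays_one_community(self):
        g = build_citation_graph(complete_graph_corpus(5))
        best_q, best_assignment = best_partition_exhaustive(g)
        assert len(set(best_assignment.values())) == 1  # no split raises Q on K5
        part = louvain(g, seed=0)
        assert part.n_communities == 1
        assert part.q == pytest.approx(best_q, abs=1e-12)

    def test_never_below_singleton_baseline(self):
        for seed in range(4):
            g = build_citation_graph(random_corpus(25, seed))
            if g.m == 0:
                continue
            singletons = {n: n for n in g.nodes}
            assert louvain(g, seed=seed).q >= modularity(g, singletons) - 1e-12

    def test_deterministic_for_fixed_seed(self):
        corpus, _ = generate_corpus(GeneratorConfig(seed=11))
        g = build_citation_graph(corpus)
        a = louvain(g, seed=5)
        b = louvain(g, seed=5)
        assert a.assignment == b.assignment
        assert a.q == b.q

    def test_edgeless_graph_is_domain_error(self):
        g = build_citation_graph(Corpus(records=[PaperRecord(id="A", year=2000)]))
        with pytest.raises(ValueError):
            louvain(g, seed=0)

    def test_planted_partition_recovery_single_config(self):
        config = GeneratorConfig(
            n_communities=4, community_sizes=(25, 25, 25, 25), p_in=0.5, p_out=0.01, seed=42
        )
        corpus, truth = generate_corpus(config)
        part = louvain(build_citation_graph(corpus), seed=1)
        assert part.n_communities == 4
        assert _ari(part, truth) >= 0.9

    def test_planted_partition_recovery_over_20_seeds(self):
        """ARI >= 0.9 on every planted 4-community graph with p_in/p_out >= 20."""
        for seed in range(20):
            config = GeneratorConfig(
                n_communities=4,
                community_sizes=(25, 25, 25, 25),
                p_in=0.5,
                p_out=0.01,
                refs_per_paper=5.0,
                seed=seed,
            )
            corpus, truth = generate_corpus(config)
            part = louvain(build_citation_graph(corpus), seed=seed)
            assert _ari(part, truth) >= 0.9

    def test_agrees_with_networkx_louvain_quality(self):
        """Independent implementation reaches a comparable local optimum."""
        corpus, _ = generate_corpus(GeneratorConfig(seed=3))
        g = build_citation_graph(corpus)
        ours = louvain(g, seed=0).q
        theirs = nx.community.modularity(
            g.undirected, nx.community.louvain_communities(g.undirected, seed=0)
        )
        assert ours == pytest.approx(theirs, abs=0.05)


class TestRankClusters:
    def _partition(self, sizes: dict) -> Partition:
        assignment = {}
        for comm, size in sizes.items():
            for i in range(size):
                assignment[f"{comm}{i:02d}"] = comm
        return Partition(assignment=assignment, q=0.0)

    def test_sorted_by_size_descending(self):
        ranked = rank_clusters(self._partition({"a": 10, "b": 30, "c": 20}))
        assert ranked.labels == {"b": 1, "c": 2, "a": 3}

    def test_single_community_gets_label_one(self):
        ranked = rank_clusters(self._partition({"only": 4}))
        assert ranked.labels == {"only": 1}

    def test_equal_sizes_tie_broken_by_smallest_member_id(self):
        ranked = rank_clusters(self._partition({"z": 5, "a": 5}))
        assert ranked.labels == {"a": 1, "z": 2}

    def test_labels_are_bijection_onto_1_to_k(self):
        corpus, _ = generate_corpus(GeneratorConfig(seed=2))
        part = rank_clusters(louvain(build_citation_graph(corpus), seed=0))
        assert sorted(part.labels.values()) == list(range(1, part.n_communities + 1))


class TestSubpartition:
    def _bridged_triangles_graph(self) -> CitationGraph:
        corpus = two_triangles_corpus()
        corpus.records[3].cited_ids = ["a3"]  # loose bridge b1 -> a3
        return build_citation_graph(corpus)

    def test_bridged_triangles_split_into_two_subclusters(self):
        g = self._bridged_triangles_graph()
        whole = Partition(assignment=dict.fromkeys(g.nodes, "c"), q=0.0, labels={"c": 1})
        sub = subpartition(g, whole, 1, seed=0)
        assert len(set(sub.labels.values())) == 2
        best_q, best = best_partition_exhaustive(g)
        assert sub.q == pytest.approx(best_q, abs=1e-12)
        assert _ari(sub, best) == pytest.approx(1.0)

    def test_clique_cluster_yields_one_subcluster(self):
        g = build_citation_graph(complete_graph_corpus(5))
        whole = Partition(assignment=dict.fromkeys(g.nodes, "c"), q=0.0, labels={"c": 1})
        sub = subpartition(g, whole, 1, seed=0)
        assert set(sub.labels.values()) == {"1-1"}

    def test_labels_take_parent_rank_form(self):
        g = self._bridged_triangles_graph()
        whole = Partition(assignment=dict.fromkeys(g.nodes, "c"), q=0.0, labels={"c": 15})
        sub = subpartition(g, whole, 15, seed=0)
        assert set(sub.labels.values()) == {"15-1", "15-2"}

    def test_edgeless_induced_subgraph_is_domain_error(self):
        corpus = Corpus(
            records=[
                PaperRecord(id="A", year=2000),
                PaperRecord(id="B", year=2001, cited_ids=["A"]),
                PaperRecord(id="C", year=2002),
            ]
        )
        g = build_citation_graph(corpus)
        part = Partition(
            assignment={"A": 1, "B": 1, "C": 2}, q=0.0, labels={1: 1, 2: 2}
        )
        with pytest.raises(ValueError):
            subpartition(g, part, 2, seed=0)
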