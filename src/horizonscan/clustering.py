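"""Modularity maximization over the citation network.

The partition quality function is Newman-Girvan modularity

    Q = (1/2m) * sum_ij (A_ij - k_i * k_j / 2m) * delta(c_i, c_j)

summed over ordered node pairs of the undirected, unweighted citation graph.
Clusters are found by the Louvain method, implemented here directly: a
local-move phase that greedily relocates nodes by modularity gain, then an
aggregation phase that collapses communities into weighted super-nodes, the
two iterated until no move improves Q.  Node visit order is shuffled with a
caller-supplied seed so runs are reproducible.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .graph_build import CitationGraph

DEFAULT_MIN_GAIN = 1e-9
DEFAULT_MAX_PASSES = 100


@dataclass
class Partition:
    """A node -> community assignment with its modularity and size ranks.

    ``labels`` maps each community id to its size rank (1 = largest) once
    :func:`rank_clusters` has run; sub-cluster partitions use strings of the
    form ``"<parent>-<rank>"`` instead of integer ranks.
    """

    assignment: dict
    q: float
    labels: dict = field(default_factory=dict)

    def communities(self) -> dict:
        """Community id -> sorted member list."""
        out: dict = {}
        for node, comm in self.assignment.items():
            out.setdefault(comm, []).append(node)
        return {c: sorted(members, key=str) for c, members in out.items()}

    def label_of(self, node):
        """Size-rank label of the community containing ``node``."""
        return self.labels[self.assignment[node]]

    def members_of_label(self, label) -> list:
        inverse = {lab: comm for comm, lab in self.labels.items()}
        if label not in inverse:
            raise KeyError(f"unknown cluster label {label!r}")
        comm = inverse[label]
        return sorted((n for n, c in self.assignment.items() if c == comm), key=str)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def modularity(graph: CitationGraph, assignment: dict) -> float:
    """Evaluate Q for an assignment covering every node of the graph."""
    m = graph.m
    if m == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    missing = set(graph.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} node(s)")
    two_m = 2.0 * m
    internal: dict = {}
    degsum: dict = {}
    for node in graph.nodes:
        c = assignment[node]
        degsum[c] = degsum.get(c, 0) + graph.degree(node)
    for u, v in graph.undirected.edges:
        if assignment[u] == assignment[v]:
            c = assignment[u]
            internal[c] = internal.get(c, 0) + 1
    q = 0.0
    for c, d in degsum.items():
        q += 2.0 * internal.get(c, 0) / two_m - (d / two_m) ** 2
    return q


def _local_moves(neighbors, self_w, deg, m2, node_comm, rng, min_gain, max_passes):
    """Phase 1: greedy node relocation.  Returns True if anything moved."""
    comm_tot = {}
    for node, c in node_comm.items():
        comm_tot[c] = comm_tot.get(c, 0.0) + deg[node]
    order = sorted(neighbors, key=str)
    moved_any = False
    for _ in range(max_passes):
        rng.shuffle(order)
        moved_this_pass = False
        for node in order:
            old = node_comm[node]
            # link weight from node into each adjacent community
            links = {}
            for nbr, w in neighbors[node].items():
                links[node_comm[nbr]] = links.get(node_comm[nbr], 0.0) + w
            comm_tot[old] -= deg[node]
            base = links.get(old, 0.0) - comm_tot[old] * deg[node] / m2
            best_comm, best_gain = old, 0.0
            for c in sorted(links, key=str):
                if c == old:
                    continue
                gain = links[c] - comm_tot[c] * deg[node] / m2 - base
                if gain > best_gain + min_gain:
                    best_comm, best_gain = c, gain
            node_comm[node] = best_comm
            comm_tot[best_comm] = comm_tot.get(best_comm, 0.0) + deg[node]
            if best_comm != old:
                moved_this_pass = moved_any = True
        if not moved_this_pass:
            break
    return moved_any


def _aggregate(neighbors, self_w, node_comm):
    """Phase 2: collapse communities into weighted super-nodes."""
    new_self: dict = {}
    new_neighbors: dict = {}
    for node, c in node_comm.items():
        new_self.setdefault(c, 0.0)
        new_self[c] += self_w.get(node, 0.0)
        new_neighbors.setdefault(c, {})
    for node, nbrs in neighbors.items():
        cu = node_comm[node]
        for nbr, w in nbrs.items():
            cv = node_comm[nbr]
            if cu == cv:
                if str(node) < str(nbr):  # count each intra edge once
                    new_self[cu] += w
            else:
                new_neighbors[cu][cv] = new_neighbors[cu].get(cv, 0.0) + w
    return new_neighbors, new_self


def louvain(
    graph: CitationGraph,
    seed: int,
    min_gain: float = DEFAULT_MIN_GAIN,
    max_passes: int = DEFAULT_MAX_PASSES,
) -> Partition:
    """Greedy modularity maximization; deterministic for a fixed seed.

    Raises ``ValueError`` on an edgeless graph, where Q is undefined.
    """
    if graph.m == 0:
        raise ValueError("Louvain requires a graph with at least one edge")
    rng = random.Random(seed)

    neighbors = {n: dict.fromkeys(graph.undirected.neighbors(n), 1.0) for n in graph.nodes}
    for n in neighbors:
        neighbors[n].pop(n, None)
    self_w = {n: 0.0 for n in neighbors}
    m2 = 2.0 * graph.m

    flat = {n: n for n in graph.nodes}  # original node -> current super-node
    while True:
        deg = {n: sum(neighbors[n].values()) + 2.0 * self_w[n] for n in neighbors}
        node_comm = {n: n for n in neighbors}
        moved = _local_moves(neighbors, self_w, deg, m2, node_comm, rng, min_gain, max_passes)
        if not moved:
            break
        flat = {orig: node_comm[super_node] for orig, super_node in flat.items()}
        neighbors, self_w = _aggregate(neighbors, self_w, node_comm)

    # canonical community ids: smallest member id of each community
    members: dict = {}
    for node, c in flat.items():
        members.setdefault(c, []).append(node)
    canon = {c: min(map(str, nodes)) for c, nodes in members.items()}
    assignment = {node: canon[c] for node, c in flat.items()}
    return Partition(assignment=assignment, q=modularity(graph, assignment))


def rank_clusters(partition: Partition) -> Partition:
    """Assign size-rank labels: 1 = most papers; ties to the smallest member id."""
    comms = partition.communities()
    ordered = sorted(comms, key=lambda c: (-len(comms[c]), str(min(map(str, comms[c])))))
    labels = {c: rank for rank, c in enumerate(ordered, 1)}
    return Partition(assignment=dict(partition.assignment), q=partition.q, labels=labels)


def subpartition(
    graph: CitationGraph,
    partition: Partition,
    cluster_label: int,
    seed: int,
) -> Partition:
    """Re-run Louvain inside one cluster; sublabels become ``"<parent>-<rank>"``."""
    members = partition.members_of_label(cluster_label)
    sub = graph.subgraph(members)
    if sub.m == 0:
        raise ValueError(f"cluster {cluster_label} has an edgeless induced subgraph")
    ranked = rank_clusters(louvain(sub, seed))
    labels = {c: f"{cluster_label}-{rank}" for c, rank in ranked.labels.items()}
    return Partition(assignment=ranked.assignment, q=ranked.q, labels=labels)
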