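"""Citation network construction.

Papers are nodes; a citation relationship is an unweighted link.  Clustering
works on the undirected view of the graph, while the directed citing->cited
view is retained for within-cluster citation counting.  Papers outside the
largest connected component are treated as digressional and dropped.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import networkx as nx

from .corpus_io import Corpus


class CitationGraph:
    """Simple unweighted citation graph with directed and undirected views.

    Wraps a :class:`networkx.DiGraph` of citing->cited arcs.  The undirected
    view collapses reciprocal arcs to one edge, so the edge count ``m`` and
    degrees ``k_i`` used by modularity always describe a simple graph.
    Node attributes carry ``year`` and ``title`` when built from a corpus.
    """

    def __init__(self, digraph: nx.DiGraph | None = None):
        self.digraph = digraph if digraph is not None else nx.DiGraph()
        self._undirected: nx.Graph | None = None

    @property
    def undirected(self) -> nx.Graph:
        if self._undirected is None:
            self._undirected = self.digraph.to_undirected(as_view=False)
        return self._undirected

    @property
    def nodes(self) -> list:
        return list(self.digraph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.digraph.number_of_nodes()

    @property
    def m(self) -> int:
        """Number of undirected edges."""
        return self.undirected.number_of_edges()

    def degree(self, node) -> int:
        return self.undirected.degree(node)

    def degrees(self) -> dict:
        return dict(self.undirected.degree())

    def year(self, node) -> int:
        return self.digraph.nodes[node].get("year", 0)

    def internal_citation_counts(self, members: set) -> dict:
        """Directed citations each member receives from other members."""
        counts = {node: 0 for node in members}
        for citing, cited in self.digraph.edges:
            if cited in counts and citing in members and citing != cited:
                counts[cited] += 1
        return counts

    def subgraph(self, nodes) -> "CitationGraph":
        return CitationGraph(nx.DiGraph(self.digraph.subgraph(nodes)))


def build_citation_graph(corpus: Corpus) -> CitationGraph:
    """Convert a corpus into the unweighted citation network.

    One node per record; one arc per resolvable (citing, cited) pair where
    both endpoints are corpus records.  Dangling cited_ids are ignored and
    duplicate citation pairs collapse to a single edge.
    """
    g = nx.DiGraph()
    ids = set()
    for rec in corpus:
        ids.add(rec.id)
        g.add_node(rec.id, year=rec.year, title=rec.title)
    for rec in corpus:
        for cited in rec.cited_ids:
            if cited in ids and cited != rec.id:
                g.add_edge(rec.id, cited)
    return CitationGraph(g)


def largest_component(graph: CitationGraph) -> CitationGraph:
    """Induced subgraph on the largest connected component (undirected).

    Ties in component size are broken by the lexicographically smallest
    member id.  An empty graph comes back empty; isolated nodes leave with
    the non-largest components.
    """
    if graph.n_nodes == 0:
        return CitationGraph()
    components = list(nx.connected_components(graph.undirected))
    best_size = max(len(c) for c in components)
    tied = [c for c in components if len(c) == best_size]
    best = min(tied, key=lambda comp: min(map(str, comp)))
    return graph.subgraph(best)


def component_fraction(n_component: int, n_total: int) -> float:
    """Percentage of retrieved papers inside the network, one decimal, half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_component <= n_total:
        raise ValueError("need 0 <= n_component <= n_total")
    pct = Decimal(100 * n_component) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def write_edge_list(graph: CitationGraph, path: str | Path) -> None:
    """Two-column TSV of directed citing->cited arcs."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for citing, cited in graph.digraph.edges:
            fh.write(f"{citing}\t{cited}\n")


def write_graphml(graph: CitationGraph, path: str | Path) -> None:
    nx.write_graphml(graph.digraph, str(path))
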