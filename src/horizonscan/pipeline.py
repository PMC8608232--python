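"""End-to-end orchestration: corpus -> network -> clusters -> reports.

One call produces the full horizon-scanning report bundle: a component
summary, a cluster table (size, median year, top TF-ICF keywords, hub
paper), a recency-trend table, a candidate table of young clusters'
sub-clusters, a GraphML export with cluster attributes, and a YAML run
manifest from which the whole run can be reproduced.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .clustering import Partition, louvain, rank_clusters, subpartition
from .corpus_io import Corpus, read_records
from .graph_build import (
    CitationGraph,
    build_citation_graph,
    component_fraction,
    largest_component,
)
from .keywords import hub_paper, pool_cluster_texts, tficf, top_keywords
from .trends import candidate_subclusters, cluster_summary, select_young_clusters

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; recorded verbatim in the output manifest."""

    input_path: str = ""
    input_format: str = "jsonl"
    citation_edges: str | None = None
    seed: int = 0
    analysis_year: int = 2020
    ngram_max: int = 2
    top_k_keywords: int = 8
    young_top_k: int = 5
    min_papers: int = 100
    min_median_year: int = 2016
    output_dir: str = "horizonscan_out"
    extra: dict = field(default_factory=dict)


class PipelineError(RuntimeError):
    """Raised with the failing stage's name when a stage aborts the run."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def export_layout(graph: CitationGraph, partition: Partition, path: str | Path) -> None:
    """GraphML with per-node cluster_label and per-edge same_cluster flag.

    Coordinates are left to external layout tools; the cluster attributes
    are what a viewer needs to color intra- vs inter-cluster links.
    """
    g = nx.DiGraph()
    for node in graph.nodes:
        g.add_node(node, cluster_label=str(partition.label_of(node)), year=graph.year(node))
    for citing, cited in graph.digraph.edges:
        g.add_edge(
            citing,
            cited,
            same_cluster=bool(partition.assignment[citing] == partition.assignment[cited]),
        )
    nx.write_graphml(g, str(path))


def _cluster_report(corpus, component, partition, config) -> pd.DataFrame:
    texts = pool_cluster_texts(corpus, partition)
    scores = tficf(texts, ngram_max=config.ngram_max) if len(texts) >= 2 else []
    by_id = corpus.by_id()
    rows = []
    for summary in cluster_summary(corpus, partition, config.analysis_year):
        label = summary.cluster_label
        kw = top_keywords(scores, label, config.top_k_keywords) if scores else []
        hub = hub_paper(component, partition, label)
        rows.append(
            {
                "cluster_label": label,
                "n_papers": summary.n_papers,
                "median_year": summary.median_year,
                "top_keywords": "; ".join(kw),
                "hub_paper_id": hub.paper_id,
                "hub_paper_title": by_id[hub.paper_id].title if hub.paper_id in by_id else "",
                "within_cluster_citations": hub.within_cluster_citations,
            }
        )
    return pd.DataFrame(rows)


def _trend_report(summaries) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_label": s.cluster_label,
                "n_papers": s.n_papers,
                "median_year": s.median_year,
                "n_last5": s.n_last5,
                "n_last3": s.n_last3,
                "ratio5": s.ratio5,
                "ratio3": s.ratio3,
            }
            for s in summaries
        ]
    )


def run_pipeline(config: PipelineConfig, corpus: Corpus | None = None) -> dict:
    """Run every stage and write the report bundle to config.output_dir.

    A corpus may be passed directly (e.g. a synthetic one); otherwise it is
    read from config.input_path.  Any stage error aborts the run with the
    stage name, removing partial outputs.  Returns the bundle as a dict of
    DataFrames plus the component summary and manifest.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            for p in written:
                p.unlink(missing_ok=True)
            raise PipelineError(name, exc) from exc

    if corpus is None:
        corpus = stage(
            "corpus_io",
            lambda: read_records(config.input_path, config.input_format, config.citation_edges),
        )

    def build():
        graph = build_citation_graph(corpus)
        component = largest_component(graph)
        if component.m == 0:
            raise ValueError("no citation links: the largest component is empty or edgeless")
        return graph, component

    graph, component = stage("graph_build", build)
    n_total = len(corpus)
    frac = component_fraction(component.n_nodes, n_total) if n_total else 0.0
    logger.info(
        "retrieved %d records; largest component %d nodes (%.1f%%), %d edges",
        n_total, component.n_nodes, frac, component.m,
    )

    partition = stage("clustering", lambda: rank_clusters(louvain(component, config.seed)))
    logger.info("found %d clusters, Q = %.4f", partition.n_communities, partition.q)

    cluster_table = stage("keywords", lambda: _cluster_report(corpus, component, partition, config))
    summaries = stage("trends", lambda: cluster_summary(corpus, partition, config.analysis_year))
    young = select_young_clusters(summaries, config.young_top_k)

    def subcluster_scan():
        rows = []
        for label in sorted(young):
            try:
                sub = subpartition(component, partition, label, config.seed)
            except ValueError:
                continue  # edgeless induced subgraph: nothing to reanalyze
            sub_members = Corpus(
                records=[r for r in corpus if r.id in sub.assignment],
                provenance=corpus.provenance,
            )
            rows.extend(cluster_summary(sub_members, sub, config.analysis_year))
        return candidate_subclusters(rows, config.min_papers, config.min_median_year)

    candidates = stage("trends", subcluster_scan)

    component_summary = {
        "n_records": n_total,
        "n_component": component.n_nodes,
        "component_fraction_pct": frac,
        "n_edges": component.m,
        "n_clusters": partition.n_communities,
        "modularity": partition.q,
    }
    trend_table = _trend_report(summaries)
    candidate_table = _trend_report(candidates)

    def write_all():
        paths = {
            "component_summary": out / "component_summary.yaml",
            "clusters": out / "clusters.csv",
            "trends": out / "trends.csv",
            "candidates": out / "candidate_subclusters.csv",
            "graphml": out / "network.graphml",
            "manifest": out / "manifest.yaml",
        }
        written.extend(paths.values())
        with paths["component_summary"].open("w") as fh:
            yaml.safe_dump(component_summary, fh, sort_keys=True)
        cluster_table.to_csv(paths["clusters"], index=False)
        trend_table.to_csv(paths["trends"], index=False)
        candidate_table.to_csv(paths["candidates"], index=False)
        export_layout(component, partition, paths["graphml"])
        manifest = {
            "config": {k: v for k, v in asdict(config).items() if k != "extra"},
            "seed": config.seed,
            "horizonscan_version": __version__,
            "young_clusters": sorted(map(str, young)),
        }
        with paths["manifest"].open("w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        return paths

    paths = stage("report", write_all)
    return {
        "component_summary": component_summary,
        "clusters": cluster_table,
        "trends": trend_table,
        "candidates": candidate_table,
        "young_clusters": young,
        "partition": partition,
        "component": component,
        "paths": paths,
    }
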