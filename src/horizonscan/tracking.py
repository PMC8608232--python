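"""Year-sliced tracking of key articles.

For each analysis year the corpus is truncated to papers published up to
that year, the citation network rebuilt, its largest component re-clustered
from scratch, and each designated key article located: which size-ranked
cluster holds it and how many citations it has received from papers in the
same cluster.  Cluster labels are NOT matched across years — each slice is
an independent analysis, so label 1 one year need not be label 1 the next;
the fluctuation of a key article's cluster rank across slices is itself the
signal of topics splitting off and growing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .clustering import louvain, rank_clusters
from .corpus_io import Corpus, filter_by_year
from .graph_build import build_citation_graph, largest_component

NOT_FOUND = "NOT_FOUND"


@dataclass(frozen=True)
class TrajectoryPoint:
    analysis_year: int
    cluster_label: object  # size-rank label, or NOT_FOUND
    citations: object  # within-cluster citation count, or NOT_FOUND


@dataclass(frozen=True)
class Trajectory:
    """Per-year location of one key article across re-analyses."""

    key_id: str
    points: tuple[TrajectoryPoint, ...]


def track_key_articles(
    corpus: Corpus, key_ids: list[str], years: list[int], seed: int
) -> list[Trajectory]:
    """Run the slice -> graph -> largest component -> Louvain pipeline per year.

    A key article absent from a slice's largest component (not yet
    published, or digressional that year) is marked NOT_FOUND.  Every slice
    uses the same seed, so the whole tracking run is deterministic.
    """
    if not years:
        raise ValueError("years must be non-empty")
    years = sorted(years)
    rows: dict[str, list[TrajectoryPoint]] = {k: [] for k in key_ids}
    for year in years:
        sliced = filter_by_year(corpus, year)
        component = largest_component(build_citation_graph(sliced))
        partition = None
        if component.m > 0:
            partition = rank_clusters(louvain(component, seed))
        for key in key_ids:
            if partition is None or key not in partition.assignment:
                rows[key].append(TrajectoryPoint(year, NOT_FOUND, NOT_FOUND))
                continue
            label = partition.label_of(key)
            members = set(partition.members_of_label(label))
            citations = component.internal_citation_counts(members)[key]
            rows[key].append(TrajectoryPoint(year, label, citations))
    return [Trajectory(key_id=k, points=tuple(rows[k])) for k in key_ids]


def trajectory_report(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table (key_id, year, cluster_label, citations), one row per
    point; NOT_FOUND kept as a literal token so no row is dropped."""
    records = [
        {
            "key_id": t.key_id,
            "year": p.analysis_year,
            "cluster_label": p.cluster_label,
            "citations": p.citations,
        }
        for t in trajectories
        for p in t.points
    ]
    return pd.DataFrame(records, columns=["key_id", "year", "cluster_label", "citations"])


def parse_trajectory_report(table: pd.DataFrame) -> list[Trajectory]:
    """Inverse of :func:`trajectory_report` (round-trips exactly)."""
    out = []
    for key, group in table.groupby("key_id", sort=False):
        points = tuple(
            TrajectoryPoint(int(row.year), row.cluster_label, row.citations)
            for row in group.itertuples()
        )
        out.append(Trajectory(key_id=str(key), points=points))
    return out
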