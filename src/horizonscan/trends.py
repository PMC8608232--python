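"""Per-cluster recency statistics and emerging-topic candidate filters.

A cluster is "young" when a large fraction of its papers appeared in the
last 3 or 5 calendar years relative to a chosen analysis year; young
clusters are re-clustered and their sub-clusters filtered by size and
median publication year to yield candidate new topics for horizon scanning.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .clustering import Partition
from .corpus_io import Corpus


def _round3(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ClusterSummary:
    """Size, publication-year statistics and recency ratios of one cluster."""

    cluster_label: object
    n_papers: int
    median_year: float
    mean_year: float
    n_last5: int
    n_last3: int
    ratio5: float
    ratio3: float


def recency_ratio(n_recent: int, n_total: int) -> float:
    """Share of a cluster's papers in a recency window, 3 decimals, half-up."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_recent <= n_total:
        raise ValueError("need 0 <= n_recent <= n_total")
    return float((Decimal(n_recent) / Decimal(n_total)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def cluster_summary(
    corpus: Corpus, partition: Partition, analysis_year: int
) -> list[ClusterSummary]:
    """One summary per ranked cluster.

    The last-5-years window is [analysis_year - 4, analysis_year] and the
    last-3-years window [analysis_year - 2, analysis_year], both inclusive;
    the median of an even-sized year list is the mean of the two central
    values and may be a half-integer.
    """
    if not partition.labels:
        raise ValueError("partition must be ranked (labels assigned) first")
    by_id = corpus.by_id()
    summaries = []
    for label in sorted(partition.labels.values(), key=str):
        years = [by_id[n].year for n in partition.members_of_label(label) if n in by_id]
        if not years:
            continue
        n = len(years)
        n5 = sum(1 for y in years if analysis_year - 4 <= y <= analysis_year)
        n3 = sum(1 for y in years if analysis_year - 2 <= y <= analysis_year)
        summaries.append(
            ClusterSummary(
                cluster_label=label,
                n_papers=n,
                median_year=float(statistics.median(years)),
                mean_year=sum(years) / n,
                n_last5=n5,
                n_last3=n3,
                ratio5=recency_ratio(n5, n),
                ratio3=recency_ratio(n3, n),
            )
        )
    return summaries


def select_young_clusters(summaries: list[ClusterSummary], top_k: int) -> set:
    """Union of the top_k clusters by 5-year ratio and the top_k by 3-year ratio.

    Ties are broken by larger cluster size, then smaller label.  With fewer
    clusters than top_k, all clusters are returned.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")

    def pick(key):
        ranked = sorted(summaries, key=lambda s: (-key(s), -s.n_papers, str(s.cluster_label)))
        return {s.cluster_label for s in ranked[:top_k]}

    return pick(lambda s: s.ratio5) | pick(lambda s: s.ratio3)


def candidate_subclusters(
    subsummaries: list[ClusterSummary],
    min_papers: int,
    min_median_year: float,
) -> list[ClusterSummary]:
    """Sub-clusters with strictly more than min_papers papers and a median
    publication year of min_median_year or later."""
    return [
        s
        for s in subsummaries
        if s.n_papers > min_papers and s.median_year >= min_median_year
    ]
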