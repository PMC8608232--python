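"""Cluster characterization: TF-ICF keywords and hub papers.

A cluster's characteristic terms are scored by term frequency times inverse
cluster frequency,

    TFICF(term i, cluster j) = tf_ij * ln(N / cf_i)

where tf_ij is the raw count of term i in cluster j's pooled text (titles +
abstracts + author keywords), N is the number of clusters and cf_i the
number of clusters whose pooled text contains the term.  A term present in
every cluster scores exactly zero, so TF-ICF surfaces what sets a cluster
apart rather than what the whole corpus talks about.

The hub paper of a cluster is the member receiving the most directed
citations from papers in the same cluster.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .clustering import Partition
from .corpus_io import Corpus
from .graph_build import CitationGraph

# word characters optionally joined by - / . ' so hyphenated gene symbols
# (pd-1, ctla-4) and tokens like ham/tsp or hf.ix survive as single terms
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:[-/.'][a-z0-9]+)*")

DEFAULT_NGRAM_MAX = 2
DEFAULT_TOP_K = 8


def load_stopwords(path=None) -> frozenset[str]:
    """Load the stopword list; the packaged English list by default."""
    if path is None:
        text = resources.files("horizonscan.data").joinpath("stopwords_en.txt").read_text("utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return frozenset(
        line.strip().lower()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )


_DEFAULT_STOPWORDS = None


def _stopwords() -> frozenset[str]:
    global _DEFAULT_STOPWORDS
    if _DEFAULT_STOPWORDS is None:
        _DEFAULT_STOPWORDS = load_stopwords()
    return _DEFAULT_STOPWORDS


def tokenize(text: str, ngram_max: int = 1, stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercased, punctuation-stripped unigrams through ngram_max-grams.

    Stopwords are removed before n-grams are formed, so a bigram may bridge
    a removed stopword.  Returns the term multiset as a list.
    """
    if ngram_max not in (1, 2, 3):
        raise ValueError("ngram_max must be 1, 2 or 3")
    if stopwords is None:
        stopwords = _stopwords()
    tokens = [t for t in _TOKEN_RE.findall(text.lower()) if t not in stopwords]
    terms = list(tokens)
    for n in range(2, ngram_max + 1):
        terms.extend(" ".join(tokens[i : i + n]) for i in range(len(tokens) - n + 1))
    return terms


@dataclass(frozen=True)
class TermScore:
    """TF-ICF of one (term, cluster) pair with its components."""

    term: str
    cluster: object
    tf: int
    cf: int
    n_clusters: int
    score: float


def pool_cluster_texts(corpus: Corpus, partition: Partition) -> dict:
    """Cluster label -> pooled titles + abstracts + author keywords."""
    pieces: dict = {label: [] for label in partition.labels.values()}
    by_id = corpus.by_id()
    for node in partition.assignment:
        rec = by_id.get(node)
        if rec is None:
            continue
        label = partition.label_of(node)
        pieces[label].append(" ".join([rec.title, rec.abstract, " ".join(rec.keywords)]))
    return {label: " ".join(texts) for label, texts in pieces.items()}


def tficf(
    cluster_texts: dict,
    ngram_max: int = DEFAULT_NGRAM_MAX,
    stopwords: frozenset[str] | None = None,
) -> list[TermScore]:
    """Score every (term, cluster) pair with tf > 0; needs at least 2 clusters."""
    n = len(cluster_texts)
    if n < 2:
        raise ValueError("TF-ICF needs at least 2 clusters (ICF is degenerate for N < 2)")
    counts = {
        label: Counter(tokenize(text, ngram_max, stopwords))
        for label, text in cluster_texts.items()
    }
    cf: Counter = Counter()
    for tf_map in counts.values():
        cf.update(tf_map.keys())
    scores = []
    for label in sorted(counts, key=str):
        for term, tf in sorted(counts[label].items()):
            scores.append(
                TermScore(
                    term=term,
                    cluster=label,
                    tf=tf,
                    cf=cf[term],
                    n_clusters=n,
                    score=tf * math.log(n / cf[term]),
                )
            )
    return scores


def top_keywords(scores: list[TermScore], cluster, k: int) -> list[str]:
    """The k highest-scoring terms of a cluster; ties broken alphabetically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    mine = [s for s in scores if s.cluster == cluster]
    if not mine:
        raise KeyError(f"unknown cluster {cluster!r}")
    mine.sort(key=lambda s: (-s.score, s.term))
    return [s.term for s in mine[:k]]


@dataclass(frozen=True)
class HubPaper:
    """The most-cited-within-cluster member of a cluster."""

    cluster: object
    paper_id: str
    within_cluster_citations: int


def hub_paper(graph: CitationGraph, partition: Partition, cluster) -> HubPaper:
    """Member receiving the most directed citations from co-members.

    Ties go to the earlier publication year, then the smaller id.
    """
    members = partition.members_of_label(cluster)  # raises KeyError if unknown
    counts = graph.internal_citation_counts(set(members))
    winner = min(members, key=lambda node: (-counts[node], graph.year(node), str(node)))
    return HubPaper(cluster=cluster, paper_id=winner, within_cluster_citations=counts[winner])
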