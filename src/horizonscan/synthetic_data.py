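"""Synthetic bibliographic corpora with planted structure.

The generator emulates the statistical shape of a large topical literature
retrieval: a citation graph with planted community structure (intra- vs
inter-community citation propensities p_in > p_out), publication years
spanning decades with per-community mass shifted toward recent years,
citations pointing only at strictly earlier papers, heavy-tailed in-degree
produced by preferential attachment, and per-community signature
vocabularies mixed into otherwise generic abstracts.  Every pipeline stage
can therefore be tested against known ground truth without any external
download.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus_io import Corpus, PaperRecord

logger = logging.getLogger(__name__)

_BACKGROUND_VOCAB = [
    "cell", "immune", "response", "antigen", "receptor", "protein",
    "expression", "mouse", "human", "analysis", "function", "pathway",
    "signal", "activation", "tissue", "model",
]


def default_vocab(n_communities: int, terms_per_community: int = 5) -> dict[int, list[str]]:
    """Distinct signature vocabularies, one list per community."""
    return {
        c: [f"topic{c}term{k}" for k in range(terms_per_community)]
        for c in range(n_communities)
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``year_skew`` is the success probability of a truncated geometric
    distribution counted back from ``year_range[1]``; larger values pile
    publication mass onto recent years.  A per-community list plants "young"
    communities.  ``key_articles`` holds (community, year, boost) triples for
    designated milestone papers whose preferential-attachment weight is
    multiplied by (1 + boost).
    """

    n_communities: int = 4
    community_sizes: tuple[int, ...] = (50, 50, 50, 50)
    p_in: float = 0.5
    p_out: float = 0.01
    year_range: tuple[int, int] = (1975, 2020)
    year_skew: float | tuple[float, ...] = 0.12
    vocab: dict[int, list[str]] | None = None
    vocab_rate: float = 3.0
    refs_per_paper: float = 6.0
    seed: int = 0
    key_articles: tuple[tuple[int, int, float], ...] = field(default=())

    def validate(self) -> "GeneratorConfig":
        if len(self.community_sizes) != self.n_communities:
            raise ValueError("community_sizes length must equal n_communities")
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (first, last) with first <= last")
        return self

    def skew_of(self, community: int) -> float:
        if isinstance(self.year_skew, (tuple, list)):
            return self.year_skew[community]
        return self.year_skew


def _sample_years(rng: np.random.Generator, config: GeneratorConfig, community: int, n: int):
    first, last = config.year_range
    span = last - first
    back = rng.geometric(config.skew_of(community), size=n) - 1
    return last - np.minimum(back, span)


def _compose_text(rng: np.random.Generator, signature: list[str], vocab_rate: float):
    n_bg = int(rng.integers(6, 12))
    words = list(rng.choice(_BACKGROUND_VOCAB, size=n_bg, replace=True))
    n_sig = int(rng.poisson(vocab_rate))
    if signature and n_sig > 0:
        words.extend(rng.choice(signature, size=n_sig, replace=True))
    rng.shuffle(words)
    return " ".join(words)


def generate_corpus(config: GeneratorConfig) -> tuple[Corpus, dict[str, int]]:
    """Generate a corpus and its ground-truth node -> community map.

    Papers are laid down in publication order; each paper makes a Poisson
    number of citation attempts (mean ``refs_per_paper``) directed only at
    strictly earlier papers.  Each attempt first picks a target community
    with weight p_in (own) or p_out (each other community) times the number
    of eligible earlier papers there, then a paper within that community
    with probability proportional to (in-degree + 1) * (1 + boost).
    Duplicate picks collapse to one edge; attempts with no eligible target
    are silently truncated with a logged warning.  The same config
    (including seed) gives a byte-identical corpus.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vocab = config.vocab if config.vocab is not None else default_vocab(config.n_communities)

    ids: list[str] = []
    community: list[int] = []
    years: list[int] = []
    boost: list[float] = []
    k = 0
    for c, size in enumerate(config.community_sizes):
        ys = _sample_years(rng, config, c, size)
        for y in ys:
            ids.append(f"P{k:05d}")
            community.append(c)
            years.append(int(y))
            boost.append(0.0)
            k += 1
    for i, (c, y, b) in enumerate(config.key_articles, 1):
        if not 0 <= c < config.n_communities:
            raise ValueError(f"key article community {c} out of range")
        ids.append(f"KEY{i:02d}")
        community.append(c)
        years.append(int(y))
        boost.append(float(b))

    n = len(ids)
    order = sorted(range(n), key=lambda i: (years[i], ids[i]))
    indeg = np.zeros(n)
    attract = 1.0 + np.asarray(boost)
    comm = np.asarray(community)
    yrs = np.asarray(years)
    cited_ids: list[list[str]] = [[] for _ in range(n)]
    truncated = 0

    for pos, i in enumerate(order):
        earlier = np.array([j for j in order[:pos] if yrs[j] < yrs[i]], dtype=int)
        n_refs = int(rng.poisson(config.refs_per_paper))
        if n_refs == 0:
            continue
        if earlier.size == 0:
            truncated += n_refs
            continue
        by_comm = {c: earlier[comm[earlier] == c] for c in range(config.n_communities)}
        comm_ids = sorted(c for c in by_comm if by_comm[c].size > 0)
        comm_w = np.array(
            [
                (config.p_in if c == comm[i] else config.p_out) * by_comm[c].size
                for c in comm_ids
            ]
        )
        if comm_w.sum() <= 0:
            truncated += n_refs
            continue
        picked: set[int] = set()
        for c in rng.choice(comm_ids, size=n_refs, replace=True, p=comm_w / comm_w.sum()):
            pool = by_comm[c]
            w = (indeg[pool] + 1.0) * attract[pool]
            picked.add(int(rng.choice(pool, p=w / w.sum())))
        for j in sorted(picked):
            cited_ids[i].append(ids[j])
            indeg[j] += 1.0

    if truncated:
        logger.warning("truncated %d citation attempt(s) with no eligible target", truncated)

    records = []
    for i in range(n):
        sig = vocab.get(community[i], [])
        title_terms = list(rng.choice(_BACKGROUND_VOCAB, size=3, replace=True))
        if sig:
            title_terms.append(str(rng.choice(sig)))
        records.append(
            PaperRecord(
                id=ids[i],
                title=" ".join(title_terms),
                abstract=_compose_text(rng, sig, config.vocab_rate),
                year=years[i],
                cited_ids=cited_ids[i],
                keywords=[str(t) for t in rng.choice(sig, size=min(2, len(sig)), replace=False)]
                if sig
                else [],
            ).validate()
        )
    records.sort(key=lambda r: r.id)
    truth = dict(zip(ids, community))
    corpus = Corpus(
        records=records,
        provenance=f"synthetic(seed={config.seed})",
        meta={"generator_config": config, "truth": truth},
    )
    return corpus, truth


def plant_key_articles(
    corpus: Corpus, specs: list[tuple[int, int, float]]
) -> Corpus:
    """Insert designated key articles and regenerate citations around them.

    Each spec is (community, year, boost); the planted paper's target weight
    is multiplied by (1 + boost), so boost 0 leaves it at chance level and a
    large boost makes it its community's hub.  Only corpora produced by
    :func:`generate_corpus` can be extended, since the regeneration needs
    the original configuration (carried in ``corpus.meta``).
    """
    config = corpus.meta.get("generator_config")
    if config is None:
        raise ValueError("plant_key_articles requires a generated corpus (missing meta config)")
    new_config = replace(config, key_articles=config.key_articles + tuple(tuple(s) for s in specs))
    planted, _ = generate_corpus(new_config)
    return planted
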