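# Methods

## The pipeline

`horizonscan` implements a horizon-scanning procedure for research
literature built on direct citation: (1) read and validate bibliographic
records; (2) build an unweighted graph with papers as nodes and citation
relationships as links, and keep only the largest connected component —
papers with no citation links into the main body of the field are treated
as digressional; (3) partition the component by modularity maximization and
rank clusters by size; (4) characterize each cluster by TF-ICF keywords and
its hub paper; (5) re-run the analysis on year-sliced sub-corpora to track
designated key articles; (6) compute per-cluster recency statistics, select
young clusters, re-cluster them, and filter their sub-clusters into
emerging-topic candidates.

Direct citation (paper A cites paper B) is used rather than co-citation or
bibliographic coupling: it is the sharpest signal for research-front
detection and requires no thresholding. Citation direction is discarded for
clustering — the modularity function is symmetric — but the directed view
is retained, because hub papers and tracking need "citations received from
papers in the same cluster".

## Modularity and Louvain

The partition quality function is Newman–Girvan modularity over ordered
node pairs of the simple undirected graph:

    Q = (1/2m) * sum_ij (A_ij - k_i k_j / 2m) * delta(c_i, c_j)

with A the 0/1 adjacency, k_i the degree, m the undirected edge count, and
delta equality of community assignments. Reciprocal citation pairs collapse
to one undirected edge so the handshake identity sum(k_i) = 2m always
holds. Q = 0 exactly for the one-community partition; Q is undefined
(domain error) on an edgeless graph.

Louvain is implemented directly rather than delegated, because the
modularity-maximization step is the analytical core of the pipeline:

- *Local-move phase*: nodes are visited in an order reshuffled each pass by
  a caller-seeded `random.Random`; a node moves to the adjacent community
  with the largest positive modularity gain (incremental formula; strictly
  greater than `min_gain_tolerance`, default 1e-9, to cut float-noise
  cycling). Candidate communities are iterated in sorted order so
  tie-breaks are deterministic.
- *Aggregation phase*: communities collapse into weighted super-nodes with
  self-loops carrying internal weight; the two phases iterate until a
  local-move phase makes no move. `max_passes` (default 100) bounds each
  local-move phase.

Equality of the incremental gains with the direct equation is a tested
invariant (the test suite compares against a literal double-loop evaluation
on graphs up to ~30 nodes at 1e-12, and against exhaustive search over all
203 partitions of 6-node toys). The resolution parameter is fixed at 1 —
plain Q with no resolution term. Community ids are canonicalized to the
smallest member id, and `rank_clusters` assigns labels by member count
(ties: smallest member id), so a fixed (graph, seed) pair yields an
identical partition every run. Sub-clustering applies the same algorithm to
one cluster's induced subgraph and labels the results `<parent>-<rank>`
(e.g. `15-1`).

Like all greedy modularity maximizers, Louvain finds a local optimum; on
planted-partition graphs with clearly separated communities it recovers the
planted structure (ARI >= 0.9 across seeds, usually exactly 1.0), but a
boundary node whose edges genuinely tie it to a neighboring community may
be placed there — that placement is the higher-Q answer, not an error.

## TF-ICF keywords and hub papers

Each cluster's pooled text is its members' titles + abstracts + author
keywords; tf_ij is the raw term count in that pool (the simplest reading,
and only the ranking matters), cf_i the number of clusters whose pool
contains the term, N the number of clusters, and the score tf * ln(N/cf)
with the natural logarithm (the base rescales all scores equally and cannot
change any ranking). N is read as the number of *clusters*: both the name
"inverse cluster frequency" and its use — measuring how specific a term is
to one cluster — require it, and any per-sentence reading would make cf/N
dimensionally inconsistent in the same formula. A term in every cluster
scores exactly 0; at least 2 clusters are required.

Tokenization lowercases, strips punctuation but keeps `-`, `/` and `.`
inside tokens so gene-symbol-like terms (pd-1, ctla-4, ham/tsp) survive as
single units, removes stopwords from a versioned packaged list (which
deliberately keeps single letters — "t" and "b" are meaningful cell-type
symbols in this domain), and then forms unigrams up to `ngram_max`-grams
(default 2, so compound terms like "suppressor cell" can surface; an
n-gram may bridge a removed stopword). No stemming or lemmatization.

The hub paper of a cluster is the member receiving the most directed
citations from co-members; ties go to the earlier publication year, then
the smaller id.

## Tracking and trends

Tracking slices the corpus at each analysis year (publication year <=
cutoff, inclusive), rebuilds the network, re-extracts the largest
component, and re-clusters *independently* with the same seed. Cluster
labels are per-slice size ranks and are deliberately not matched across
years: rank fluctuation is itself informative (a topic splitting off into
its own cluster lowers the parent's rank and later rises as it grows). A
key article absent from a slice's largest component is reported as the
literal token `NOT_FOUND`. At the corpus's final year the slice is the
whole corpus, so the tracking output must (and is tested to) coincide with
the full-corpus analysis.

Cluster recency uses inclusive calendar windows anchored at an explicit
`analysis_year`: last-5 = [analysis_year-4, analysis_year], last-3 =
[analysis_year-2, analysis_year]. The explicit anchor avoids any ambiguity
about whether windows count from the newest paper or a retrieval date.
Ratios are rounded half-up to 3 decimals and component percentages half-up
to 1 decimal, matching the reporting precision used for worked-example
checks. Median publication year of an even-sized cluster is the mean of the
two central values and may be a half-integer. Young-cluster selection takes
the union of the top-k clusters by 5-year ratio and by 3-year ratio (ties:
larger cluster, then smaller label); the sub-cluster candidate filter keeps
sub-clusters with strictly more than `min_papers` papers and median year
`>= min_median_year` — strict on size, inclusive on year, following the
usual "more than N papers, year Y or later" phrasing of such criteria.

## Synthetic corpus generator

The generator emulates the statistical shape of a large topical retrieval
so every stage is testable against ground truth:

- **Communities**: `n_communities` of given sizes (default 4 x 50 — large
  enough for stable recovery, small enough that the full test suite runs in
  seconds); `p_in`/`p_out` (default 0.5/0.01) control topical mixing.
- **Years**: per community, a truncated geometric distribution counted back
  from the last year of `year_range` (default 1975–2020, spanning the
  decades a mature field accumulates); `year_skew` (default 0.12) is the
  geometric parameter, and a per-community list plants young communities.
- **Citations**: papers are laid down in publication order; each makes
  Poisson(`refs_per_paper`, default 6) attempts, each attempt only at
  strictly earlier papers. An attempt first chooses a target community with
  weight p_in (own) or p_out (other) times the eligible-pool size, then a
  paper within it with probability proportional to (in-degree + 1) times
  the paper's boost factor — preferential attachment, giving the
  heavy-tailed within-cluster citation counts that make hub detection
  meaningful. Duplicate picks collapse to one edge; attempts with no
  eligible target are truncated with a warning.
- **Text**: abstracts are background terms shared by all communities plus
  Poisson(`vocab_rate`, default 3) draws from the community's signature
  vocabulary; titles and author keywords carry signature terms too.

For equal-sized communities the expected intra-community edge share is
p_in / (p_in + p_out (C-1)) in the large-pool limit. Finite corpora sit a
few percent below it: the earliest papers of a community may have no
earlier co-members (their attempts necessarily go elsewhere or truncate),
and duplicate collapse trims concentrated intra picks slightly more than
dispersed inter picks. The Monte-Carlo invariant test therefore runs in a
regime where pools are large relative to `refs_per_paper`.

`plant_key_articles` inserts designated milestone papers. Because citations
are sampled jointly, planting regenerates the corpus from its recorded
configuration (carried in `Corpus.meta`) with the planted papers included,
their attachment weight multiplied by (1 + boost): boost 0 leaves a planted
paper at exactly chance attractiveness, boost ~50 reliably makes an early
paper its community's hub. The same config (seed included) always yields a
byte-identical corpus.

What the generator does *not* emulate — and hence what passing tests do not
show about real corpora: real linguistic abstracts (tokens are drawn from
small vocabularies), citations to literature outside the corpus, author/
journal/affiliation structure, retrieval-query bias, database lag between
publication and indexing, and communities that merge or genuinely overlap.
Recovery results on planted graphs bound the algorithmic behavior, not the
noisiness of real bibliographic data.

## Problem sizes and runtime choices

The shipped tests and the acceptance script use corpora of 200–400 papers
with 4 planted communities — the smallest sizes at which community
recovery, hub formation and young-cluster detection are all
unambiguous — so the full suite completes in well under a minute. The
implementation itself is dictionary-based and handles graphs several orders
of magnitude larger; nothing in the pipeline is specific to the test scale.

## Known limitations

- Greedy Louvain gives a local optimum; no restarts or Leiden-style
  refinement are attempted (the seed makes any single run reproducible).
- Overlapping communities and cross-year cluster identity matching are out
  of scope; trajectories report per-slice ranks only.
- The record model carries no author/journal fields; summaries by journal
  or affiliation would need a model extension.
- MEDLINE input needs a sidecar citation edge file, since the format itself
  carries no reference lists.
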