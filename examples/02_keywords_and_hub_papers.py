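"""Characterize clusters by TF-ICF keywords and hub papers.

TF-ICF = tf * ln(N / cf) scores how specific a term is to one cluster; the
hub paper is the member most cited from inside its own cluster.  On a
synthetic corpus the top keywords should be the planted signature terms.
"""

from horizonscan import (
    GeneratorConfig,
    build_citation_graph,
    generate_corpus,
    hub_paper,
    largest_component,
    louvain,
    pool_cluster_texts,
    rank_clusters,
    tficf,
    top_keywords,
)

corpus, truth = generate_corpus(GeneratorConfig(seed=1))
component = largest_component(build_citation_graph(corpus))
partition = rank_clusters(louvain(component, seed=1))

scores = tficf(pool_cluster_texts(corpus, partition), ngram_max=2)
for label in sorted(partition.labels.values()):
    kw = top_keywords(scores, label, k=5)
    hub = hub_paper(component, partition, label)
    print(f"cluster {label}: keywords {', '.join(kw)}")
    print(f"            hub {hub.paper_id} "
          f"({hub.within_cluster_citations} within-cluster citations)")
# Each cluster's keywords are its community's planted topicNtermK vocabulary
# (generic background words score ~0 because they occur in every cluster),
# and the hub is the paper that accumulated the most internal citations.
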