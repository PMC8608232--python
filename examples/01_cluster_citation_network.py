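"""Build a citation network from a synthetic corpus and cluster it.

Generates a corpus with four planted communities, keeps the largest
connected component, partitions it by Louvain modularity maximization and
prints cluster sizes, modularity Q, and recovery against the planted truth.
"""

from collections import Counter

from sklearn.metrics import adjusted_rand_score

from horizonscan import (
    GeneratorConfig,
    build_citation_graph,
    component_fraction,
    generate_corpus,
    largest_component,
    louvain,
    rank_clusters,
)

corpus, truth = generate_corpus(GeneratorConfig(seed=1))
graph = build_citation_graph(corpus)
component = largest_component(graph)
print(f"{len(corpus)} records; largest component {component.n_nodes} nodes "
      f"({component_fraction(component.n_nodes, len(corpus))}%), {component.m} edges")

partition = rank_clusters(louvain(component, seed=1))
print(f"Louvain found {partition.n_communities} clusters, Q = {partition.q:.4f}")
for label in sorted(partition.labels.values()):
    members = partition.members_of_label(label)
    top_comm = Counter(truth[m] for m in members).most_common(1)[0]
    print(f"  cluster {label}: {len(members)} papers, "
          f"{top_comm[1]}/{len(members)} from planted community {top_comm[0]}")

nodes = sorted(partition.assignment)
ari = adjusted_rand_score([truth[n] for n in nodes], [partition.assignment[n] for n in nodes])
print(f"adjusted Rand index vs planted communities: {ari:.3f}")
# Q near 0.6 and ARI near 1 mean the partition is strongly modular and
# recovers the planted structure almost exactly.
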