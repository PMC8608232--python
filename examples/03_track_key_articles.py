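"""Track planted key articles across year-sliced re-analyses.

Plants one strongly boosted early milestone paper and one later ordinary
one, then re-runs the whole pipeline on papers published up to each
analysis year and reports the cluster (size rank) containing each key
article and its within-cluster citation count.
"""

from horizonscan import (
    GeneratorConfig,
    generate_corpus,
    plant_key_articles,
    track_key_articles,
    trajectory_report,
)

base, _ = generate_corpus(GeneratorConfig(seed=1))
corpus = plant_key_articles(base, [(0, 1978, 50.0), (1, 2015, 5.0)])

years = [1990, 2000, 2010, 2020]
trajectories = track_key_articles(corpus, ["KEY01", "KEY02"], years, seed=1)
print(trajectory_report(trajectories).to_string(index=False))
# KEY02 is NOT_FOUND before its 2015 publication year; KEY01's within-
# cluster citation count grows as its community accumulates papers.  Labels
# are per-slice size ranks and are not matched across years.
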