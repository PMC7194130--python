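"""Partition compositional dissimilarity among summits into turnover and
nestedness, pairwise and for the whole summit set at once."""

import numpy as np

from summitveg import PairCounts, generate_survey, pair_counts, pairwise_partition
from summitveg.beta import average_linkage_cluster, component_distance_matrix, multisite_partition
from summitveg.community import build_matrix
from summitveg.synthetic import SurveyDesign

# pairwise: two aspects sharing 2 species, with 1 and 2 exclusives
counts = pair_counts([1, 1, 1, 0, 0], [0, 1, 1, 1, 1])
part = pairwise_partition(counts)
print(f"pair counts a={counts.a} b={counts.b} c={counts.c}")
print(f"pairwise: bsor={part.bsor:.4f} bsim={part.bsim:.4f} bsne={part.bsne:.4f}")
# bsor is total Sørensen dissimilarity; bsim the replacement share; bsne the
# richness-difference (nestedness) share. They always satisfy bsor = bsim + bsne.

# multi-site over the four summits of a synthetic resurvey
observations, _, _ = generate_survey(SurveyDesign(seed=1))
matrix = build_matrix(observations, grouping="summit", year_filter=2014, mode="incidence")
multi = multisite_partition(matrix)
print(f"\nmulti-site over {len(matrix.values)} summits: "
      f"bsor={multi.bsor:.4f} bsim={multi.bsim:.4f} bsne={multi.bsne:.4f}")
print("nestedness exceeds turnover" if multi.bsne > multi.bsim else "turnover dominates")
# With strongly nested summit pools, richness difference (bsne), not species
# replacement, carries most of the among-summit dissimilarity.

# UPGMA clustering of aspect-level turnover
aspects = build_matrix(observations, grouping="aspect", year_filter=2014, mode="incidence")
dend = average_linkage_cluster(component_distance_matrix(aspects, "bsim"))
print(f"\nUPGMA merge heights (turnover): {np.round(dend.merge_heights, 3)}")
print(dend.to_newick()[:100] + "...")
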