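"""Cluster a protein family across identity thresholds and pick one.

Builds a small synthetic family of 12 proteins in 3 subfamilies, clusters
it at every threshold from 80 to 100 %, and asks for the recommended
operating point — the threshold where the cluster count rises fastest.
"""

from envprimer import gen_gene_family, recommend_threshold, sweep_thresholds
from envprimer.synthfix import FamilySpec

family = gen_gene_family(FamilySpec(seed=7))
sweep = sweep_thresholds(family.aa_records)

print("threshold  n_clusters")
for t, n in zip(sweep.thresholds, sweep.n_clusters):
    print(f"{t:9.0f}  {n}")

best = recommend_threshold(sweep)
print(f"\nrecommended threshold: {best:.0f}%")
print(f"clusters at that threshold: {len(sweep.clusters_at(best))}")
# The curve stays at 3 (the planted subfamilies) until within-subfamily
# variation starts splitting clusters; the recommendation sits at the onset
# of that rise, keeping one cluster per subfamily.
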