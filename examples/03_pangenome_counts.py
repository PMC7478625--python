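"""Core/pan-genome co-occurrence counting over an orthologue table.

Clusters the synthetic cohort's proteins with the built-in reciprocal-
best-hit stand-in, then counts the genus core, the species-by-species
shared-orthologue matrix (diagonal = per-species core) and the exclusive
Venn regions.
"""

from panvita.pangenome import (
    cluster_orthologues,
    core_genome,
    intersection_counts,
    pairwise_shared_matrix,
)
from panvita.synth import SimulationConfig, simulate_pangenome

config = SimulationConfig(seed=42)
genomes, truth = simulate_pangenome(config)

table = cluster_orthologues([genomes[g] for g in truth.roster])
print(f"orthologue groups: {len(table.groups)} (true families: {len(truth.families)})")

core = core_genome(table, truth.roster)
print(f"genus core (groups in all {len(truth.roster)} genomes): {len(core)}")

taxa: dict[str, list[str]] = {}
for g in truth.roster:
    taxa.setdefault(truth.species_map[g], []).append(g)
shared = pairwise_shared_matrix(table, taxa).pairwise
print("species-level shared-orthologue matrix (diagonal = species core):")
print(shared.to_string())

venn = intersection_counts(table, taxa)
exclusive = {tuple(sorted(k)): v for k, v in venn.items() if v}
print("exclusive Venn regions (species subsets -> group counts):")
for subset, count in sorted(exclusive.items(), key=lambda kv: (len(kv[0]), kv[0])):
    print(f"  {'&'.join(subset)}: {count}")
# The all-species region is the genus core at species-level presence; the
# regions sum to the pan-genome (groups present in >=1 species).
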