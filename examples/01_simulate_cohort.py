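"""Generate a synthetic six-genome cohort with known ground truth.

Three species with two strains each; every genome carries the genus core,
its species accessory and a few private genes, plus the pathway gene
complement drawn by the synthesis/salvage strategy lottery. All files the
downstream readers consume are written to ./scratch_cohort/.
"""

from panvita.synth import (
    SimulationConfig,
    simulate_evidence,
    simulate_pangenome,
    write_cohort,
)

config = SimulationConfig(seed=42)
genomes, truth = simulate_pangenome(config)
evidence = simulate_evidence(genomes, truth, config)
write_cohort("scratch_cohort", genomes, truth, evidence)

n_genes = {g: len(recs) for g, recs in genomes.items()}
print(f"genomes: {len(truth.roster)}  (species: {len(set(truth.species_map.values()))})")
print(f"genes per genome: {min(n_genes.values())}-{max(n_genes.values())}")
print(f"true gene families: {len(truth.families)}")
complete = (truth.pathway_truth == "complete").sum().sum()
print(f"complete pathway cells in truth: {complete} of {truth.pathway_truth.size}")
print("files written to scratch_cohort/ (FASTA, feature tables, hit tables, truth)")
# The truth bundle is what the recovery tests compare against: family
# membership, per-gene function, the pathway status matrix and the
# vitamin strategy table.
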