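"""Between-population differentiation: FST, AIM screening, NJ tree, MDS.

Simulates five populations at a known Balding–Nichols differentiation
(F = 0.08) over 30 DIP loci, then estimates the pairwise bias-corrected FST
matrix, ranks loci by locus-specific FST (ancestry-informative-marker
screening), builds the neighbor-joining tree, and ordinates the populations
in two dimensions with SMACOF.
"""

import numpy as np

import indelpop as ip
from indelpop.io import distance_matrix_to_string

rng = np.random.default_rng(1)
ancestral = [np.array([p, 1 - p]) for p in rng.uniform(0.2, 0.8, size=30)]
freq_table, _ = ip.simulate_balding_nichols(
    ancestral, fst_target=0.08, sizes=[500] * 5, seed=2,
    population_names=["Pop1", "Pop2", "Pop3", "Pop4", "Pop5"],
)

matrix = ip.fst_matrix(freq_table)
print("pairwise bias-corrected FST (PHYLIP square):")
print(distance_matrix_to_string(matrix))

aims = ip.locus_specific_fst(freq_table)
print("top 5 loci by locus-specific FST (AIM candidates):")
print(aims.head(5).to_string(index=False))

tree = ip.neighbor_joining(matrix)
print("\nneighbor-joining tree:")
print(ip.to_newick(tree))

mds = ip.smacof_mds(matrix)
print(f"\nSMACOF 2-D ordination (stress-1 = {mds.stress:.4f}):")
for label, (x, y) in zip(mds.labels, mds.coords):
    print(f"  {label}: ({x:+.4f}, {y:+.4f})")
print("\nPopulations drawn from the same ancestral pool at F = 0.08 sit at "
      "comparable\npairwise distances; the stress says how faithfully the "
      "plane preserves them.")
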