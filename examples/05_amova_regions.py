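"""Locus-by-locus AMOVA across regional subsamples.

Simulates the study-shaped panel (631 individuals, 30 DIP loci, three
regional labels) under panmixia and partitions allelic variance among/within
regions.  With no true regional structure, Phi_ST hovers near zero and the
permutation p-values are spread over (0, 1) — the expected picture for a
genetically homogeneous population.
"""

import numpy as np

import indelpop as ip
from indelpop.popstruct import amova_frame

table = ip.simulate_study_panel(seed=8)
results = ip.amova_locus(table, n_perm=999, seed=9)
df = amova_frame(results)
print(df.round(4).to_string(index=False))

print(f"\nphi_ST range: {df['phi_st'].min():+.4f} .. {df['phi_st'].max():+.4f}")
print(f"p-value range: {df['p_perm'].min():.4f} .. {df['p_perm'].max():.4f}")
print(f"loci with p < 0.05: {int((df['p_perm'] < 0.05).sum())} of {len(df)}")
print("\nUnder panmixia essentially all variance lies within regions; "
      "a handful of\nnominal rejections at alpha = 0.05 is the expected "
      "false-positive load.")
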