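"""Haplotype diversity and differentiation on a simulated island model.

Generates a 16-population haplotype count table with expected
differentiation 1/(1 + alpha) = 0.25, then computes per-population gene
diversity, H_S / H_T, G_ST, N_ST with its permutation comparison, and
Jost's D with jackknife standard errors.
"""

import numpy as np

from haploniche import HaplotypeDistances, diversity_analysis
from haploniche.simulate import IslandModelSpec, simulate_haplotype_table

table = simulate_haplotype_table(IslandModelSpec(
    n_populations=16, n_per_population=16, n_haplotypes=8, alpha=3.0, seed=42))

# haplotypes one mutation step apart along a chain
steps = np.abs(np.subtract.outer(np.arange(table.n_haplotypes),
                                 np.arange(table.n_haplotypes))).astype(float)
dist = HaplotypeDistances(steps, table.haplotype_ids)

res = diversity_analysis(table, dist, n_perm=2000,
                         rng=np.random.default_rng(0))

print("per-population He:",
      " ".join(f"{h:.3f}" for h in res.per_population_He))
print(f"H_S = {res.HS:.3f} (SE {res.standard_errors['HS']:.3f})")
print(f"H_T = {res.HT:.3f} (SE {res.standard_errors['HT']:.3f})")
print(f"G_ST = {res.GST:.3f}   {res.ordered_label} = {res.ordered_stat:.3f}"
      f"   Jost's D = {res.jost_D:.3f}")
print(f"P({res.ordered_label} > G_ST by chance) = {res.permutation_p:.3f}")
print()
print("G_ST near 1/(1+alpha) = 0.25 reflects the simulated island-model")
print("differentiation; a non-significant permutation p means haplotype")
print("relatedness adds no geographic signal beyond frequencies alone")
print("(no phylogeographic structure), as expected for unordered draws.")
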