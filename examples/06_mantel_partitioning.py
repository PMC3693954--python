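"""Partitioning genetic structure between geography and ecology.

Builds the three distance matrices of the landscape-genetics workflow —
pairwise F_ST, great-circle km, and Euclidean distance on the first two
environmental PCA axes — for 16 simulated populations whose
differentiation follows geography, then runs Mantel and partial Mantel
tests.
"""

import numpy as np
import pandas as pd

from haploniche import (
    HaplotypeTable, PopulationMeta, OccurrenceSet,
    great_circle_matrix, ecological_distance_matrix, pairwise_fst,
    pca_ordination, mantel, partial_mantel,
)

rng = np.random.default_rng(5)
n_pops = 16
lons = np.sort(rng.uniform(98, 106, n_pops))
lats = rng.uniform(23, 28, n_pops)
meta = [PopulationMeta(f"p{i + 1}", "x", lons[i], lats[i], 1500.0, 16, 16)
        for i in range(n_pops)]

# haplotype frequencies drift along the east-west axis -> isolation by distance
counts = np.zeros((n_pops, 6), dtype=int)
for i in range(n_pops):
    centre = (lons[i] - 98) / 8 * 5
    w = np.exp(-0.5 * (np.arange(6) - centre) ** 2 / 1.2**2)
    counts[i] = rng.multinomial(16, w / w.sum())
table = HaplotypeTable(counts[:, counts.sum(0) > 0],
                       [m.population_id for m in meta],
                       [f"h{j}" for j in np.flatnonzero(counts.sum(0) > 0)])

# environment partially tracks longitude
env = pd.DataFrame({
    "longitude": lons, "latitude": lats, "altitude": 1500.0,
    "bio_a": 0.8 * lons + rng.normal(0, 1, n_pops),
    "bio_b": rng.normal(0, 1, n_pops),
    "bio_c": lats + rng.normal(0, 1, n_pops),
})
pca = pca_ordination(OccurrenceSet(env))

gen = pairwise_fst(table)
geo = great_circle_matrix(meta)
eco = ecological_distance_matrix(pca, np.arange(n_pops))

r_gg, p_gg = mantel(gen, geo, n_perm=5000, rng=rng)
r_ge, p_ge = mantel(gen, eco, n_perm=5000, rng=rng)
pr_gg, pp_gg = partial_mantel(gen, geo, eco, n_perm=5000, rng=rng)
pr_ge, pp_ge = partial_mantel(gen, eco, geo, n_perm=5000, rng=rng)

print(f"Mantel  F_ST ~ geography:             r = {r_gg:.2f}  p = {p_gg:.4f}")
print(f"Mantel  F_ST ~ ecology:               r = {r_ge:.2f}  p = {p_ge:.4f}")
print(f"partial F_ST ~ geography | ecology:   r = {pr_gg:.2f}  p = {pp_gg:.4f}")
print(f"partial F_ST ~ ecology  | geography:  r = {pr_ge:.2f}  p = {pp_ge:.4f}")
print()
print("Differentiation was generated by geographic drift alone, so the")
print("geography association survives partialling out ecology, while the")
print("ecology association (inherited from its correlation with longitude)")
print("weakens once geography is controlled.")
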