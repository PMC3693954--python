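"""AMOVA and the SAMOVA group search on a three-region world.

Builds 16 populations in three geographic regions, each dominated by its
own haplotype lineage, decomposes the molecular variance, and lets the
simulated-annealing scan over K = 2..5 rediscover the regional grouping.
"""

import numpy as np

from haploniche import HaplotypeTable, PopulationMeta, amova, scan_K

rng = np.random.default_rng(13)
groups = [range(0, 5), range(5, 11), range(11, 16)]
counts = np.zeros((16, 6), dtype=int)
for g, members in enumerate(groups):
    for i in members:
        p = np.full(6, 0.01)
        p[2 * g], p[2 * g + 1] = 0.75, 0.21
        counts[i] = rng.multinomial(16, p / p.sum())
table = HaplotypeTable(counts[:, counts.sum(axis=0) > 0],
                       [f"p{i + 1}" for i in range(16)],
                       [f"h{j + 1}" for j in range(np.sum(counts.sum(axis=0) > 0))])

meta = []
for g, centre in enumerate([(98.5, 25.5), (101.5, 26.0), (104.5, 24.5)]):
    for k in range([5, 6, 5][g]):
        i = len(meta)
        meta.append(PopulationMeta(f"p{i + 1}", f"pop{i + 1}",
                                   centre[0] + rng.uniform(-0.8, 0.8),
                                   centre[1] + rng.uniform(-0.8, 0.8),
                                   1800.0, 16, 16))

one = amova(table, n_perm=1000, rng=rng)
print("one-level AMOVA:")
for c in one.components:
    print(f"  {c['name']:<32} df={c['df']:<4} SS={c['SS']:8.3f} "
          f"var={c['variance']:.3f}  {c['percent']:6.2f}%")
print(f"  F_ST = {one.F_statistics['FST']:.3f}  (p = {one.p_values['FST']:.4f})")

best = scan_K(table, None, meta, K_range=range(2, 6), n_restarts=6,
              n_iter=250, n_null=100, rng=np.random.default_rng(1))
print("\nSAMOVA F_CT by K:",
      "  ".join(f"K={k}: {f:.3f}" for k, f in best.FCT_by_K))
print(f"best K = {best.K}, F_CT = {best.FCT:.3f}, p = {best.p_value:.3f}")
print("partition:", best.partition)

two = amova(table, grouping=best.partition, n_perm=500, rng=rng)
print("\nhierarchical AMOVA under the SAMOVA grouping:")
for c in two.components:
    print(f"  {c['name']:<32} {c['percent']:6.2f}%")
print("F statistics:", {k: round(v, 3) for k, v in two.F_statistics.items()})
print()
print("Most variance sits among populations/groups because each region is")
print("nearly fixed for its own lineage; the K=3 partition recovered by the")
print("annealing matches the three generating regions.")
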