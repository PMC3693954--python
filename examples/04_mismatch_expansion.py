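"""Mismatch distribution and the sudden-expansion test.

Simulates a coalescent sample that underwent a demographic expansion
(tau = 3, theta 0.3 -> 40), fits the sudden-expansion model by least
squares, and tests goodness of fit with a parametric bootstrap; the
raggedness index is reported alongside.
"""

import numpy as np

from haploniche import fit_expansion, ssd_pvalue, raggedness
from haploniche.simulate import simulate_expansion_sample

n = 40
d = simulate_expansion_sample(n, tau=3.0, theta0=0.3, theta1=40.0, seed=8)
pairs = d[np.triu_indices(n, 1)]
counts = np.bincount(pairs)
obs = counts / counts.sum()

print("observed mismatch distribution (classes 0..%d):" % (len(obs) - 1))
print("  " + " ".join(f"{f:.3f}" for f in obs))

fit = fit_expansion(obs)
p = ssd_pvalue(n, fit, n_boot=200, rng=np.random.default_rng(0))
r = raggedness(obs)
print(f"\nfitted tau = {fit.tau:.2f}  theta0 = {fit.theta0:.3f}  "
      f"theta1 = {fit.theta1:.1f}")
print(f"SSD = {fit.SSD:.5f}   P(SSD) = {p:.3f}   raggedness = {r:.3f}")
print()
print("A unimodal mismatch distribution with mode near tau and a")
print("non-significant P(SSD) is the signature of a past sudden")
print("demographic expansion; stationary populations give jagged,")
print("multimodal distributions with high raggedness.")
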