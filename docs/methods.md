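# Methods

This note records the statistical models implemented in `haploniche`,
the estimator variants chosen where the literature offers several, the
numerical choices that affect results, and what the synthetic-data
generators do and do not emulate.

## Haplotype diversity and differentiation

All markers are haploid organellar data, so "gene diversity" plays the
role of expected heterozygosity. Per-population diversity uses the
unbiased estimator `He = n/(n-1) (1 - Σ p_i²)`. Species-level
quantities follow the Pons–Petit family: `H_S` is the equal-weight mean
of the per-population `He`; `H_T = 1 - Σ x̄_j² + H_S/(k·ñ)` with `x̄_j`
the unweighted mean frequency of haplotype j over the k populations and
`ñ` the harmonic-mean sample size; `G_ST = (H_T - H_S)/H_T`.
Populations are weighted equally regardless of n (sample sizes here are
near-constant; weighting would change third-decimal results only).

The ordered statistics replace the heterozygosity kernel by
frequency-weighted mean inter-haplotype distances: `v_S` and `v_T` are
the distance analogues of `H_S`, `H_T` and `N_ST = (v_T - v_S)/v_T`.
With mutation-step distances this is N_ST; with summed squared repeat
differences over cpSSR loci it is R_ST (repeat counts from fragment
sizes assuming mononucleotide motifs; motif length configurable). The
statistic is invariant to rescaling the distance matrix, and with an
all-equal off-diagonal matrix it reduces algebraically to G_ST — both
properties are under test. The phylogeographic-structure test permutes
haplotype identities on the distance matrix and reports the fraction of
permuted ordered statistics at least as large as the observed one.

Jost's D uses the nearly unbiased multi-population form
`D = k/(k-1) · (H_T - H_S)/(1 - H_S)` with the same unbiased `H_S`,
`H_T`. Standard errors for all table statistics are
leave-one-population-out jackknives (undefined and reported as missing
below three populations).

A consequence of unbiasedness worth noting: populations with
*identical observed* compositions yield slightly negative `G_ST` and
`D` (the correction terms overshoot zero). Negative estimates are
reported as computed, never truncated.

## AMOVA and SAMOVA

Individuals are expanded from haplotype counts (haploid data), and the
entries of the haplotype distance matrix are treated as squared
distances, so mutation-step counts plug in directly. Sums of squares
use the standard identity `SS(unit) = Σ_{i<j} δ²_ij / n`; variance
components come from the nested mean squares with the usual unequal-n
coefficients; `F_ST`, `F_SC`, `F_CT` are ratios of those components.
Permutation schemes: individuals among populations (F_ST), whole
populations among groups (F_CT), individuals among populations within
groups (F_SC); p-values use the (hits+1)/(n+1) convention. Negative
components are retained. The count-matrix shortcut is verified against
a brute-force individual-level computation to 1e-9.

SAMOVA builds a Delaunay neighbour graph on population coordinates
(collinear layouts fall back to an augmented 2-nearest-neighbour
graph), grows a random contiguous K-partition per restart, and anneals
by single-population border moves with Metropolis acceptance and
geometric cooling (factor 0.95; the initial temperature is set from the
spread of F_CT over random partitions). Contiguity is enforced on every
accepted state. Ties between equal-F_CT partitions break toward the
lexicographically smallest label vector for reproducibility. The
p-value compares the best F_CT against random contiguous partitions.
On six-population test cases the search provably attains the
exhaustively enumerated optimum across seeds.

Default distances: mutation steps for mtDNA (indel blocks recoded as
below), haplotype identity for cpSSR — both overridable, and reports
carry the metric label, since published pipelines are often silent on
this choice.

## Median-joining networks

Declared indel blocks collapse to one multistate character whose states
are the distinct block sequences, all at mutual distance 1 — distinct
indel types are treated as independent insertion events, which gives
the most compact network. Remaining variable columns are unit-step site
characters, so haplotype distance is Hamming on the recoded matrix.

The construction iterates: build the ε-relaxed minimum spanning network
(ε = 0 by default); for every connected triple propose its
quasi-median(s) (per-character majority; full ties branch into all
three states, capped at six tie characters); accept a median only if it
strictly reduces the exact MST weight of the node set; repeat to a
fixed point, then drop medians made redundant by later additions.
Because Hamming distance is a metric, a degree-2 median can never
reduce the MST weight, so surviving medians have degree ≥ 3. On
tree-like (infinite-sites) data the result is exactly the generating
topology. Haplotypes observed once are excluded before network analysis
(`exclude_singletons`). Outgroup haplotypes are ordinary nodes flagged
`outgroup=true`; layout and circle sizes are left to downstream tools
(frequencies are exported as node attributes).

## Mismatch distributions and sudden expansion

For a pairwise coalescent with mutation parameter stepping from θ0 to
θ1 at mutational time τ, the expected mismatch probabilities are

    F(i) = F_E(i, θ1) · P[Γ(i+1) ≤ τ(1+1/θ1)]
         + e^{−τ(1+1/θ1)} Σ_{j≤i} τ^j/j! · F_E(i−j, θ0),

with `F_E(i, θ) = θ^i/(1+θ)^{i+1}` the stationary geometric law; the
vector is renormalized over the truncation 0..d_max, where d_max is the
largest observed class plus a margin of 5 empty classes. The closed
form is verified in the tests against direct numerical integration of
the Poisson kernel over the two-phase coalescent density.

Fitting minimizes the sum of squared deviations (SSD) by multi-start
Levenberg–Marquardt on log-transformed parameters with θ1 = θ0 + Δ
(eight documented starts; Δ ≥ 0 enforces θ1 ≥ θ0). A single-class
observed distribution is degenerate: τ equals the class value, both θ
at the zero bound, flagged.

`P(SSD)` is a parametric bootstrap: coalescent samples of the same size
are simulated under the fitted parameters (msprime; haploid population
of size θ, per-lineage mutation rate 1/2, instantaneous size change at
generation τ, infinite-sites mutations — this scaling makes the
expected stationary pairwise difference equal θ and puts the step at
pairwise distance τ), each simulated distribution is refitted (all
three parameters, warm-started at the fitted values), and p is the
fraction of simulated SSDs ≥ the observed. The infinite-sites
approximation is applied to binary-coded cpSSR data as well — a
documented approximation, adequate at the low divergences involved.
Under the fitted model the bootstrap p-value is uniform (KS-tested).

Raggedness is the sum of squared successive differences of the class
frequencies with zero classes flanking both ends of the support (so a
point mass scores 2 and a k-class uniform scores 2/k²).

cpSSR binary coding: per locus with repeat range [m, M], an allele of a
repeats becomes an (M−m)-bit block with the first a−m bits set;
Hamming distance between coded rows equals the summed stepwise
distance, an identity asserted in the tests.

## Niche space and divergence tests

Variable screening removes collinearity greedily: while any pair has
|r| ≥ 0.70, the member of the worst pair with the larger mean absolute
correlation is dropped (deterministic order). Ecotype clustering is a
full-covariance Gaussian mixture over a k range with BIC selection and
MAP assignment — a seeded, reproducible stand-in for the CF-tree
TwoStep procedure of commercial software, agreeing with it on
well-separated data (which is the regime the acceptance properties
test). DFA is two-group canonical discriminant analysis: Wilks'
λ = |W|/|T| with the exact F transformation for two groups, and
standardized canonical coefficients (unit-normed); singular
within-group scatter is ridge-regularized with a warning.

PCA is correlation-matrix PCA (population SD scaling, uniform row
weights), so eigenvalues sum to the number of variables and
`var_explained = λ/p`; the retention rule everywhere is eigenvalue > 1.
Between-class inertia is the between-class share of total inertia of
the scaled data, tested by label permutation.

The background divergence test fits the PCA on the pooled occurrence +
background environments of the two ecotypes (pooling was chosen over
occurrence-only fitting; the axes must embed both clouds for d_n and
d_b to be comparable). Per retained axis, d_n is the mean |difference
of mean scores| over 1000 draws of 75% occurrence subsamples, d_b the
same over background subsamples, and the verdict is: divergence if
mean d_n exceeds the upper 95% bound of the d_b distribution *and* the
occurrence score difference is significant by a 10⁴-permutation t-test;
conservatism if mean d_n falls below the lower bound; otherwise not
significant. The permutation gate keeps the null divergence rate at the
nominal level even though d_n and d_b have different sampling
variances (occurrence samples are much smaller than background
samples); the null false-positive rate is measured in the acceptance
suite. d_n/d_b are absolute differences; no sign convention is
imposed.

## SDM and overlap

The SDM is a Gibbs distribution over background cells:
`P(cell) ∝ exp(w·f)` with standardized linear and quadratic features of
each environmental variable and an L1 penalty (weight 0.05, smoothed
for gradients), optimized by L-BFGS. This captures the core of the
maximum-entropy approach; hinge/product features and adaptive
regularization of the full Maxent program are deliberately out of
scope, so overlap values published from Maxent runs are qualitative
references rather than reproduction targets. Backgrounds are uniform
seeded samples of unmasked cells (10 000 by default, or all cells on
small rasters). Suitability is the normalized exponential over unmasked
cells (sums to 1).

AUC is the rank statistic of presence scores against background-cell
scores, reported for the 75% training and 25% held-out splits, with the
conventional poor/useful/good bands. Threshold selection maximizes
sensitivity + specificity by default; a flag provides the literal
minimum-sum variant for workflows that specify it that way.

Overlap on co-registered surfaces renormalized over the intersection
mask: Schoener's `D = 1 − ½Σ|p₁−p₂|` and Warren's Hellinger-based
`I = 1 − ½Σ(√p₁−√p₂)²`. The identity test pools the two occurrence
sets, reshuffles them into pseudo-sets of the original sizes, refits
both SDMs per replicate, and ranks the observed (D, I) in the null
(one-tailed; small p rejects niche identity).

## Mantel tests

Mantel r is the Pearson correlation of off-diagonal vectorizations;
partial Mantel correlates the residuals of A and B after regressing
each on the control matrix (Smouse–Long–Sokal). Significance permutes
objects (rows and columns together) of the first matrix, one-tailed for
positive association — the isolation-by-distance convention. Genetic
distance is pairwise two-population AMOVA F_ST (negatives retained),
geographic distance is haversine km (Earth radius 6371.0088), and
ecological distance is Euclidean on the first two PCA axes evaluated at
the population sites. Null p-values are uniform (KS-tested); the plain
Mantel r is cross-checked against an independent implementation in the
test suite.

## Synthetic data: what it emulates and what it does not

* **Island-model tables**: population frequencies are Dirichlet(α·base)
  with total concentration α, counts multinomial; the frequency-level
  differentiation is exactly `1/(1+α)`, which makes recovery tests
  sharp. The closed form is an infinite-population limit: with k
  populations the expected G_ST is depressed by O(1/k), so recovery is
  tested at 300 populations × 100 individuals (200 replicates), where
  the finite-k bias is far below the Monte-Carlo resolution. This
  generator has no mutation model and no spatial autocorrelation: it
  validates frequency statistics, not phylogeographic inference.
* **Sequence sets**: infinite-sites mutations on star or chain
  genealogies with a fixed number of mutations per edge — exactly the
  regime where a median-joining network must reproduce the true tree.
  No recombination, no homoplasy.
* **Expansion samples**: msprime coalescent with an instantaneous size
  change, in the mutation scaling described above. Real organellar data
  add mutation-rate heterogeneity and selection, which the generator
  omits; passing recovery/calibration tests demonstrates correctness of
  the estimator, not robustness to model violation.
* **Niche worlds**: environmental layers are low-order trend surfaces
  plus spatially smoothed noise, standardized; ecotype niches are
  Gaussians in environment space with centres 3 SD apart (pairwise),
  breadth 0.25 SD, and 0.15 SD observation noise on recorded
  environments — calibrated to the cleanly separated ecotype structure
  that motivates this analysis style (near-perfect cluster recovery,
  between-class inertia well above chance). Real climate layers have
  stronger cross-correlations and sampling bias that the generator does
  not model.

Analyses of real published datasets require the original
per-population count tables and occurrence/environment tables; where
only printed summaries are available, the package reproduces the
quantities those summaries determine (for example, every per-population
gene diversity whose haplotype composition is fixed by the printed
sample size and haplotype number).

## Problem sizes and determinism

Simulation-based checks run at deliberately moderate sizes chosen to
give stable verdicts: 100–200 replicates for recovery and calibration
properties, 99-replicate inner bootstraps for p-value uniformity
(KS at α = 0.01 is insensitive to this granularity), 50 seeds for the
annealing-vs-enumeration equivalence. Production defaults in
`RunConfig` are higher (10⁴ permutations and bootstrap replicates, 100
identity pseudoreplicates, 1000 background points and resamples).
Every stochastic stage takes an explicit seed or generator;
`RunConfig.rng(stage)` derives per-stage seeds deterministically from
the master seed so partial reruns reproduce, and reports are written
with sorted keys so identical runs are byte-identical.

## Known limitations

* SAMOVA contiguity uses the Delaunay graph of population coordinates,
  not geographic barriers; with few populations several partitions can
  tie and the lexicographic tie-break is arbitrary (but reproducible).
* The SDM's feature set (linear + quadratic) cannot represent
  multimodal responses within one ecotype.
* Wilks' λ p-values use the exact two-group F transformation but assume
  multivariate normality within clusters; for strongly non-Gaussian
  clusters the permutation machinery elsewhere in the package is the
  safer reference.
* Mismatch fitting on very small samples (n < 10) is weakly identified
  in θ1; the bootstrap p-value remains calibrated but τ̂ is noisy.
* Converting τ to calendar time (τ = 2ut) is interpretive and outside
  the package's scope.
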