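"""Haplotype diversity and differentiation statistics.

Implements the unbiased (sample-size corrected) estimator family of Pons
& Petit for haploid organellar data: per-population gene diversity,
average within-population diversity H_S, total diversity H_T, the
frequency-only fixation index G_ST, its distance-weighted ("ordered")
analogues N_ST (nucleotide steps) and R_ST (squared repeat differences),
Jost's differentiation index D, leave-one-population-out jackknife
standard errors, and the permutation test asking whether the ordered
statistic exceeds G_ST (the classic phylogeographic-structure test).

Populations are weighted equally regardless of sample size, and negative
estimates (possible under the unbiased corrections) are reported as
computed rather than truncated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class HaplotypeTable:
    """Populations x haplotypes count matrix.

    Counts, not frequencies, are the stored unit; frequencies are always
    derived on demand to avoid rounding drift.
    """

    counts: np.ndarray
    population_ids: list[str]
    haplotype_ids: list[str]
    genome: str = "mt"  # "mt" | "cp"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D populations x haplotypes matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.any(self.counts != np.round(self.counts)):
                raise ValueError("haplotype counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("haplotype counts must be non-negative")
        npop, nhap = self.counts.shape
        if len(self.population_ids) != npop:
            raise ValueError("population_ids length does not match counts rows")
        if len(self.haplotype_ids) != nhap:
            raise ValueError("haplotype_ids length does not match counts columns")
        if len(set(self.population_ids)) != npop:
            raise ValueError("duplicate population ids")
        if nhap < 1:
            raise ValueError("at least one haplotype required")
        if np.any(self.counts.sum(axis=1) < 1):
            bad = [self.population_ids[i] for i in np.flatnonzero(self.counts.sum(axis=1) < 1)]
            raise ValueError(f"populations with zero sampled individuals: {bad}")
        if np.any(self.counts.sum(axis=0) == 0):
            bad = [self.haplotype_ids[j] for j in np.flatnonzero(self.counts.sum(axis=0) == 0)]
            raise ValueError(f"all-zero haplotype columns retained: {bad}")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    @property
    def n_haplotypes(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def frequencies(self) -> np.ndarray:
        return self.counts / self.sample_sizes[:, None]

    def pooled_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_populations(self, ids: list[str]) -> "HaplotypeTable":
        """Restrict to the given populations, dropping emptied haplotypes."""
        idx = [self.population_ids.index(i) for i in ids]
        sub = self.counts[idx]
        keep = sub.sum(axis=0) > 0
        return HaplotypeTable(sub[:, keep], list(ids),
                              [h for h, k in zip(self.haplotype_ids, keep) if k],
                              genome=self.genome)


@dataclass
class HaplotypeDistances:
    """Symmetric inter-haplotype distance matrix with zero diagonal.

    metric_tag records the distance semantics: nucleotide mutation steps
    for mitotypes ("nucleotide_steps"), summed squared repeat differences
    for chlorotypes ("squared_repeat"), plain 0/1 ("identity") or Hamming
    distance on a binary recoding ("hamming_binary"). Squared metrics are
    allowed, so the triangle inequality is not required.
    """

    matrix: np.ndarray
    haplotype_ids: list[str]
    metric_tag: str = "nucleotide_steps"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if len(self.haplotype_ids) != n:
            raise ValueError("haplotype_ids length does not match matrix")
        if np.any(self.matrix < 0):
            raise ValueError("distances must be non-negative")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.matrix)) > 1e-12):
            raise ValueError("distance matrix diagonal must be zero")

    @classmethod
    def identity(cls, haplotype_ids: list[str]) -> "HaplotypeDistances":
        n = len(haplotype_ids)
        return cls(1.0 - np.eye(n), list(haplotype_ids), metric_tag="identity")

    def aligned_to(self, table: HaplotypeTable) -> np.ndarray:
        """Distance matrix reordered to the table's haplotype order."""
        try:
            idx = [self.haplotype_ids.index(h) for h in table.haplotype_ids]
        except ValueError as exc:
            raise ValueError(f"distance matrix does not cover table haplotypes: {exc}") from exc
        return self.matrix[np.ix_(idx, idx)]


@dataclass
class DiversityResult:
    """Species- or group-level differentiation summary."""

    per_population_He: list[float]
    HS: float
    HT: float
    GST: float
    ordered_stat: float | None
    jost_D: float
    standard_errors: dict[str, float | None] = field(default_factory=dict)
    permutation_p: float | None = None
    ordered_label: str = "NST"


def gene_diversity(counts_one_pop) -> float:
    """Unbiased gene diversity n/(n-1) * (1 - sum p_i^2) of one population."""
    c = np.asarray(counts_one_pop, dtype=float)
    if c.size == 0:
        raise ValueError("empty count vector")
    if np.any(c < 0):
        raise ValueError("negative counts")
    n = c.sum()
    if n < 1:
        raise ValueError("no individuals sampled")
    if n == 1:
        warnings.warn("gene diversity of a single individual is 0 by convention")
        return 0.0
    p = c / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def _within_pop_diversities(table: HaplotypeTable) -> np.ndarray:
    n = table.sample_sizes.astype(float)
    p = table.frequencies()
    return n / (n - 1.0) * (1.0 - np.sum(p * p, axis=1))


def hs_ht_gst(table: HaplotypeTable) -> tuple[float, float, float]:
    """Unbiased H_S, H_T and G_ST = (H_T - H_S)/H_T.

    H_S is the equal-weight mean of sample-size-corrected within-population
    diversities; H_T is one minus the summed squared mean frequencies plus
    the small-sample correction H_S/(k * n_harmonic).
    """
    k = table.n_populations
    if k < 2:
        raise ValueError("need >= 2 populations; use gene_diversity for one")
    n = table.sample_sizes.astype(float)
    if np.any(n < 2):
        raise ValueError("every population needs n >= 2 for the unbiased estimators")
    hs = float(np.mean(_within_pop_diversities(table)))
    xbar = table.frequencies().mean(axis=0)
    n_harm = k / np.sum(1.0 / n)
    ht = float(1.0 - np.sum(xbar * xbar) + hs / (n_harm * k))
    gst = 0.0 if ht == 0 else float((ht - hs) / ht)
    return hs, ht, gst


def ordered_differentiation(table: HaplotypeTable, dist: HaplotypeDistances) -> float:
    """N_ST (or R_ST) = (v_T - v_S)/v_T, the distance-weighted G_ST analogue.

    v statistics replace the heterozygosity kernel 1 - sum p^2 by the
    frequency-weighted mean inter-haplotype distance; with an all-equal
    off-diagonal distance matrix this reduces exactly to G_ST.
    """
    d = dist.aligned_to(table)
    k = table.n_populations
    if k < 2:
        raise ValueError("need >= 2 populations")
    n = table.sample_sizes.astype(float)
    if np.any(n < 2):
        raise ValueError("every population needs n >= 2")
    p = table.frequencies()
    v_pop = n / (n - 1.0) * np.einsum("ij,jl,il->i", p, d, p)
    vs = float(np.mean(v_pop))
    xbar = p.mean(axis=0)
    n_harm = k / np.sum(1.0 / n)
    vt = float(xbar @ d @ xbar + vs / (n_harm * k))
    if vt == 0:
        return 0.0
    return float((vt - vs) / vt)


def permutation_compare(table: HaplotypeTable, dist: HaplotypeDistances,
                        n_perm: int = 10_000,
                        rng: np.random.Generator | None = None) -> float:
    """P-value for "ordered statistic > G_ST" by permuting haplotype identities.

    Haplotype labels are shuffled on the distance matrix (which preserves
    G_ST and the frequency structure but destroys any association between
    molecular similarity and co-occurrence); p is the proportion of
    permuted N_ST/R_ST values >= the observed one.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = rng or np.random.default_rng()
    d = dist.aligned_to(table)
    obs = ordered_differentiation(table, HaplotypeDistances(d, table.haplotype_ids, dist.metric_tag))
    nh = table.n_haplotypes
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(nh)
        dp = d[np.ix_(perm, perm)]
        stat = ordered_differentiation(
            table, HaplotypeDistances(dp, table.haplotype_ids, dist.metric_tag))
        if stat >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def jost_d(table: HaplotypeTable) -> float:
    """Multi-population Jost's D, the k/(k-1)-scaled ratio (H_T-H_S)/(1-H_S).

    Uses the same nearly-unbiased H_S / H_T estimators as hs_ht_gst, so the
    result measures effective differentiation of haplotype frequencies
    independently of within-population diversity.
    """
    k = table.n_populations
    hs, ht, _ = hs_ht_gst(table)
    if hs >= 1.0:
        return 0.0
    return float(k / (k - 1.0) * (ht - hs) / (1.0 - hs))


def jackknife_se(statistic, table: HaplotypeTable) -> float | None:
    """Leave-one-population-out jackknife SE of a table statistic.

    Returns None (missing marker) for fewer than 3 populations, where the
    jackknife variance is undefined for a between-population statistic.
    """
    k = table.n_populations
    if k < 3:
        return None
    vals = []
    for i in range(k):
        ids = [p for j, p in enumerate(table.population_ids) if j != i]
        vals.append(statistic(table.subset_populations(ids)))
    vals = np.asarray(vals, dtype=float)
    return float(np.sqrt((k - 1.0) / k * np.sum((vals - vals.mean()) ** 2)))


def diversity_analysis(table: HaplotypeTable,
                       dist: HaplotypeDistances | None = None,
                       n_perm: int = 10_000,
                       rng: np.random.Generator | None = None) -> DiversityResult:
    """Full differentiation summary: He per population, H_S/H_T/G_ST,
    ordered statistic with permutation comparison, Jost's D, jackknife SEs."""
    he = [gene_diversity(row) for row in table.counts]
    hs, ht, gst = hs_ht_gst(table)
    d_jost = jost_d(table)
    ordered = perm_p = None
    label = "NST" if table.genome == "mt" else "RST"
    ses: dict[str, float | None] = {
        "HS": jackknife_se(lambda t: hs_ht_gst(t)[0], table),
        "HT": jackknife_se(lambda t: hs_ht_gst(t)[1], table),
        "GST": jackknife_se(lambda t: hs_ht_gst(t)[2], table),
        "jost_D": jackknife_se(jost_d, table),
    }
    if dist is not None:
        ordered = ordered_differentiation(table, dist)
        perm_p = permutation_compare(table, dist, n_perm=n_perm, rng=rng)
        ses[label] = jackknife_se(
            lambda t: ordered_differentiation(t, dist), table)
    return DiversityResult(per_population_He=he, HS=hs, HT=ht, GST=gst,
                           ordered_stat=ordered, jost_D=d_jost,
                           standard_errors=ses, permutation_p=perm_p,
                           ordered_label=label)
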