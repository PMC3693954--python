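"""Mismatch distributions and the sudden-expansion demographic model.

The mismatch distribution is the histogram of pairwise differences among
sampled haplotypes. Under a sudden demographic expansion (mutation
parameter theta jumping from theta0 to theta1 at mutational time tau in
the past) the expected distribution has the closed form obtained by
integrating a Poisson mutation kernel over the two-phase pairwise
coalescent: with F_E(i, theta) = theta^i / (1 + theta)^(i+1) the
stationary geometric law,

    F(i) = F_E(i, theta1) * P[Gamma(i+1) <= tau (1 + 1/theta1)]
         + exp(-tau (1 + 1/theta1)) * sum_{j<=i} tau^j/j! * F_E(i-j, theta0).

Parameters are fitted by least squares (sum of squared deviations, SSD)
by multi-start Levenberg-Marquardt on log-transformed parameters
(theta1 = theta0 + delta enforces theta1 >= theta0). Goodness of fit is
tested by a parametric bootstrap: coalescent samples of the same size
are simulated under the fitted model, refitted, and the p-value is the
fraction of simulated SSDs at least as large as the observed one.
Harpending's raggedness index quantifies the jaggedness of the observed
distribution (high for stationary populations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc, gammaln

from .haplostats import HaplotypeDistances

# truncation margin beyond the largest observed difference class
D_MAX_PAD = 5


@dataclass
class MismatchResult:
    observed: np.ndarray
    tau: float
    theta0: float
    theta1: float
    SSD: float
    p_SSD: float | None = None
    raggedness: float | None = None
    degenerate: bool = False


def mismatch_observed(individual_haplotypes, dist: HaplotypeDistances) -> np.ndarray:
    """Normalized frequency vector of pairwise distances over classes 0..max.

    individual_haplotypes are per-individual haplotype labels (or indices
    into dist); all n(n-1)/2 unordered pairs contribute.
    """
    idx = [dist.haplotype_ids.index(h) if isinstance(h, str) else int(h)
           for h in individual_haplotypes]
    n = len(idx)
    if n < 2:
        raise ValueError("need >= 2 individuals for a mismatch distribution")
    d = dist.matrix[np.ix_(idx, idx)]
    iu = np.triu_indices(n, k=1)
    pairs = np.rint(d[iu]).astype(int)
    counts = np.bincount(pairs)
    return counts / counts.sum()


def expansion_expected(tau: float, theta0: float, theta1: float, d_max: int) -> np.ndarray:
    """Expected mismatch probabilities for classes 0..d_max under sudden
    expansion, renormalized over the truncation."""
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be non-negative")
    i = np.arange(d_max + 1)
    out = np.zeros(d_max + 1)
    # recent phase: coalescence before the expansion event
    if theta1 > 0:
        log_fe1 = i * np.log(theta1) - (i + 1) * np.log1p(theta1)
        rate = tau * (1.0 + 1.0 / theta1)
        out += np.exp(log_fe1) * gammainc(i + 1, rate)
        tail = np.exp(-rate)
    elif tau > 0:
        # theta1 = 0: coalescence is instantaneous, a point mass at zero
        out[0] = 1.0
        return out
    else:
        tail = 1.0  # theta1 = 0, tau = 0: the stationary theta0 phase only
    # ancient phase: Poisson(tau) mutations plus stationary tail at theta0
    if tail > 0:
        if theta0 > 0:
            log_fe0 = i * np.log(theta0) - (i + 1) * np.log1p(theta0)
        else:
            log_fe0 = np.where(i == 0, 0.0, -np.inf)
        with np.errstate(divide="ignore"):
            log_pois = np.where(
                (i == 0) & (tau == 0), 0.0,
                i * np.log(tau if tau > 0 else 1.0) - gammaln(i + 1))
        if tau == 0:
            conv = np.exp(log_fe0)
        else:
            conv = np.convolve(np.exp(log_pois), np.exp(log_fe0))[:d_max + 1]
        out += tail * conv
    s = out.sum()
    if s <= 0:
        raise ValueError("degenerate expected distribution")
    return out / s


_STARTS = [
    # (tau multiplier of the observed mean, theta0, delta = theta1 - theta0)
    (0.5, 0.1, 1.0), (0.5, 1.0, 5.0), (1.0, 0.1, 1.0), (1.0, 0.5, 10.0),
    (1.5, 0.01, 2.0), (1.5, 1.0, 20.0), (2.0, 0.1, 5.0), (0.25, 0.01, 0.5),
]


def _residuals(params_log: np.ndarray, observed: np.ndarray) -> np.ndarray:
    tau, theta0, delta = np.exp(np.clip(params_log, -30, 30))
    exp = expansion_expected(tau, theta0, theta0 + delta, len(observed) - 1)
    return observed - exp


def _ssd(params_log: np.ndarray, observed: np.ndarray) -> float:
    return float(np.sum(_residuals(params_log, observed) ** 2))


def fit_expansion(observed, n_starts: int = 8,
                  extra_starts: list[tuple[float, float, float]] | None = None,
                  maxiter: int = 600) -> MismatchResult:
    """Least-squares fit of (tau, theta0, theta1) to an observed mismatch
    frequency vector, by multi-start Levenberg-Marquardt on log parameters.

    The support is padded by a margin of empty classes beyond the largest
    observed difference so the truncation does not clip the model tail.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.ndim != 1 or obs.size < 1:
        raise ValueError("observed must be a frequency vector")
    obs = obs / obs.sum()
    support = np.flatnonzero(obs > 0)
    if support.size == 1:
        cls = int(support[0])
        return MismatchResult(observed=obs, tau=float(cls), theta0=0.0,
                              theta1=0.0, SSD=0.0, degenerate=True)
    obs = np.concatenate([obs, np.zeros(D_MAX_PAD)])
    mean_d = float(np.sum(np.arange(obs.size) * obs))
    starts = [np.log([max(tm * mean_d, 1e-3), t0, dl])
              for (tm, t0, dl) in _STARTS[:n_starts]]
    for (tau_s, t0_s, t1_s) in extra_starts or []:
        starts.insert(0, np.log([max(tau_s, 1e-3), max(t0_s, 1e-3),
                                 max(t1_s - t0_s, 1e-3)]))
    best_ssd, best_x = np.inf, starts[0]
    for x0 in starts:
        res = least_squares(_residuals, x0, args=(obs,), method="lm",
                            xtol=1e-10, ftol=1e-12, max_nfev=maxiter)
        ssd = float(np.sum(res.fun**2))
        if ssd < best_ssd:
            best_ssd, best_x = ssd, res.x
    tau, theta0, delta = np.exp(np.clip(best_x, -30, 30))
    return MismatchResult(observed=obs, tau=float(tau), theta0=float(theta0),
                          theta1=float(theta0 + delta), SSD=best_ssd)


def ssd_pvalue(sample_size: int, fitted: MismatchResult,
               observed_SSD: float | None = None, n_boot: int = 10_000,
               rng: np.random.Generator | None = None,
               refit_starts: int = 2) -> float:
    """Parametric-bootstrap goodness-of-fit p-value for the expansion model.

    Coalescent samples of the given size are simulated under the fitted
    (tau, theta0, theta1), each simulated mismatch distribution is
    refitted, and p is the fraction of simulated SSDs >= the observed SSD.
    """
    from .simulate import simulate_expansion_sample

    if n_boot < 100:
        warnings.warn("n_boot < 100 gives a coarse bootstrap p-value")
    rng = rng or np.random.default_rng()
    ssd_obs = fitted.SSD if observed_SSD is None else observed_SSD
    warm = [(fitted.tau, fitted.theta0, fitted.theta1)]
    hits = 0
    for _ in range(n_boot):
        seed = int(rng.integers(2**31 - 1))
        dmat = simulate_expansion_sample(sample_size, fitted.tau, fitted.theta0,
                                         fitted.theta1, seed=seed)
        iu = np.triu_indices(sample_size, k=1)
        counts = np.bincount(dmat[iu].astype(int))
        sim = fit_expansion(counts / counts.sum(), n_starts=refit_starts,
                            extra_starts=warm, maxiter=300)
        if sim.SSD >= ssd_obs - 1e-15:
            hits += 1
    return (hits + 1) / (n_boot + 1)


def raggedness(observed) -> float:
    """Raggedness index: sum of squared successive differences of the
    class frequencies, with zero classes flanking both ends of the
    observed support."""
    x = np.asarray(observed, dtype=float)
    if x.size < 1:
        raise ValueError("empty mismatch distribution")
    padded = np.concatenate([[0.0], x, [0.0]])
    return float(np.sum(np.diff(padded) ** 2))


def cpssr_binary_code(genotypes: np.ndarray, motif_length: int = 1) -> np.ndarray:
    """Binary recoding of cpSSR allele sizes for mismatch analysis.

    Each locus with repeat-count range [m, M] becomes an (M - m)-column
    block in which an allele of a repeats sets the first (a - m) positions
    to 1, so the Hamming distance between two coded rows equals the
    summed stepwise distance over loci.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be haplotypes x loci")
    reps = g / motif_length
    off = reps - reps.min(axis=0)
    if np.any(np.abs(off - np.round(off)) > 1e-6):
        raise ValueError("allele size differences are not multiples of the motif length")
    off = np.round(off).astype(int)
    blocks = []
    for locus in range(off.shape[1]):
        span = off[:, locus].max()
        if span == 0:
            continue
        block = (np.arange(span)[None, :] < off[:, locus][:, None]).astype(np.int8)
        blocks.append(block)
    if not blocks:
        return np.zeros((g.shape[0], 0), dtype=np.int8)
    return np.concatenate(blocks, axis=1)
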