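"""Synthetic data generators with the statistical structure the analyses
assume, so every pipeline stage is testable without external downloads.

Four worlds are generated: (1) multi-population haplotype count tables
under a Dirichlet-multinomial island model whose expected differentiation
is 1/(1 + alpha) in the concentration parameter alpha — a closed form
that makes parameter-recovery tests exact; (2) aligned sequence sets
evolved by infinite-sites mutations on star or chain topologies, whose
true genealogy a median-joining network must recover; (3) pairwise
difference samples from a coalescent with an instantaneous population
size change (the sudden-expansion model, simulated via msprime in
mutation-scaled time so tau maps directly); and (4) smooth environmental
rasters carrying displaced Gaussian niches with occurrence points
sampled proportionally to suitability, with truth labels retained.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import msprime
from scipy.ndimage import gaussian_filter

from .haplostats import HaplotypeTable
from .haplonet import SequenceSet
from .raster import EnvRaster
from .niche import OccurrenceSet


@dataclass
class IslandModelSpec:
    """Dirichlet-multinomial island model.

    Population haplotype frequencies are Dirichlet(alpha * base) draws
    around shared base frequencies; counts are multinomial. Expected
    differentiation (G_ST-like) is 1/(1 + alpha).
    """

    n_populations: int = 16
    n_per_population: int = 16
    n_haplotypes: int = 13
    alpha: float = 1.0
    base_frequencies: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if min(self.n_populations, self.n_per_population, self.n_haplotypes) < 1:
            raise ValueError("counts must be >= 1")
        if self.base_frequencies is not None:
            b = np.asarray(self.base_frequencies, dtype=float)
            if b.size != self.n_haplotypes or np.any(b <= 0):
                raise ValueError("base_frequencies must be positive, one per haplotype")
            if abs(b.sum() - 1.0) > 1e-8:
                raise ValueError("base_frequencies must sum to 1")
            self.base_frequencies = b / b.sum()


@dataclass
class NicheSimSpec:
    """Smooth environmental world with displaced Gaussian niches."""

    n_rows: int = 40
    n_cols: int = 40
    xllcorner: float = 97.0
    yllcorner: float = 22.0
    cellsize: float = 0.25
    n_variables: int = 4
    n_ecotypes: int = 3
    niche_separation: float = 3.0   # pairwise distance of niche centres, in env SD
    niche_sd: float = 0.25          # Gaussian niche breadth in env space
    n_occurrences: int = 50         # per ecotype
    noise_sd: float = 0.15          # observation noise added to occurrence env
    seed: int = 0

    def __post_init__(self):
        if self.n_ecotypes < 1 or self.n_occurrences < 1:
            raise ValueError("counts must be >= 1")
        if self.niche_sd <= 0:
            raise ValueError("niche_sd must be positive")


def simulate_haplotype_table(spec: IslandModelSpec) -> HaplotypeTable:
    """Dirichlet-multinomial haplotype count table (deterministic per seed)."""
    rng = np.random.default_rng(spec.seed)
    base = (spec.base_frequencies if spec.base_frequencies is not None
            else np.full(spec.n_haplotypes, 1.0 / spec.n_haplotypes))
    counts = np.empty((spec.n_populations, spec.n_haplotypes), dtype=np.int64)
    for i in range(spec.n_populations):
        # total concentration alpha gives E[differentiation] = 1/(1 + alpha)
        p = rng.dirichlet(spec.alpha * base)
        counts[i] = rng.multinomial(spec.n_per_population, p)
    keep = counts.sum(axis=0) > 0
    return HaplotypeTable(counts[:, keep],
                          [f"pop{i + 1}" for i in range(spec.n_populations)],
                          [f"H{j + 1}" for j in np.flatnonzero(keep)],
                          genome="mt")


def simulate_sequences(n_haplotypes: int, n_sites: int, tree: str = "star",
                       mutations_per_edge: int = 1, seed: int = 0) -> SequenceSet:
    """Aligned haplotype sequences under infinite-sites mutation on a star
    (all tips radiate from one ancestor) or chain (stepping-stone path)
    topology. Each edge carries mutations_per_edge unique substitutions,
    so the true genealogy is recoverable exactly from the alignment."""
    if tree not in ("star", "chain"):
        raise ValueError("tree must be 'star' or 'chain'")
    n_mut = n_haplotypes * mutations_per_edge
    if n_sites < n_mut:
        raise ValueError(f"n_sites={n_sites} cannot host {n_mut} unique mutations")
    rng = np.random.default_rng(seed)
    sites = rng.choice(n_sites, size=n_mut, replace=False)
    ancestor = np.array(list("A" * n_sites))
    seqs = []
    current = ancestor.copy()
    for h in range(n_haplotypes):
        block = sites[h * mutations_per_edge:(h + 1) * mutations_per_edge]
        if tree == "star":
            seq = ancestor.copy()
            seq[block] = "G"
        else:
            current = current.copy()
            current[block] = "G"
            seq = current
        seqs.append("".join(seq))
    return SequenceSet(names=[f"H{h + 1}" for h in range(n_haplotypes)],
                       sequences=seqs)


def simulate_expansion_sample(n: int, tau: float, theta0: float, theta1: float,
                              seed: int = 0) -> np.ndarray:
    """Pairwise difference matrix for n haploid lineages under a sudden
    expansion from theta0 to theta1 at mutational time tau.

    Scaling: haploid population size is theta (per-lineage mutation rate
    1/2 per unit time), so the expected pairwise difference of a
    stationary population equals theta and the size step sits at
    generation tau (pairwise mutational distance tau).
    """
    if min(tau, theta0, theta1) < 0:
        raise ValueError("parameters must be non-negative")
    theta0 = max(theta0, 1e-6)
    theta1 = max(theta1, 1e-6)
    demography = msprime.Demography()
    demography.add_population(name="pop", initial_size=theta1)
    if tau > 0:
        demography.add_population_parameters_change(
            time=tau, initial_size=theta0, population="pop")
    ts = msprime.sim_ancestry(samples=n, demography=demography, ploidy=1,
                              sequence_length=1.0, random_seed=(seed % (2**31 - 1)) + 1)
    ts = msprime.sim_mutations(ts, rate=0.5, discrete_genome=False,
                               model=msprime.BinaryMutationModel(),
                               random_seed=(seed % (2**31 - 1)) + 1)
    G = ts.genotype_matrix()  # sites x samples
    if G.size == 0:
        return np.zeros((n, n), dtype=np.int64)
    diff = (G[:, :, None] != G[:, None, :]).sum(axis=0)
    return diff.astype(np.int64)


def _trend_surface(rows: int, cols: int, coeffs, rng: np.random.Generator,
                   smooth_sigma: float = 3.0) -> np.ndarray:
    y, x = np.mgrid[0:rows, 0:cols]
    xn = (x - x.mean()) / max(x.std(), 1.0)
    yn = (y - y.mean()) / max(y.std(), 1.0)
    a, b, c, d = coeffs
    surface = a * xn + b * yn + c * xn * yn + d * (xn**2 - yn**2)
    noise = gaussian_filter(rng.standard_normal((rows, cols)), smooth_sigma)
    noise /= max(noise.std(), 1e-9)
    surface = surface + 0.5 * noise
    return (surface - surface.mean()) / surface.std()


def simulate_niche_world(spec: NicheSimSpec) -> tuple[EnvRaster, OccurrenceSet]:
    """Environmental raster plus labelled occurrences.

    Environmental layers are smooth low-order trend surfaces with
    spatially correlated noise, standardized to zero mean and unit SD.
    Each ecotype has a niche centre displaced by niche_separation SD
    along a distinct direction in environment space; occurrence cells
    are drawn with probability proportional to the Gaussian suitability
    of the ecotype, and the recorded environment adds observation noise.
    Truth labels are kept in an 'ecotype' column.
    """
    rng = np.random.default_rng(spec.seed)
    layers = {}
    for v in range(spec.n_variables):
        coeffs = rng.uniform(-1, 1, size=4)
        coeffs[v % 4] += 1.5  # make trends distinct across variables
        layers[f"env{v + 1}"] = _trend_surface(spec.n_rows, spec.n_cols,
                                               coeffs, rng)
    raster = EnvRaster(spec.xllcorner, spec.yllcorner, spec.cellsize,
                       layers=layers)
    env = raster.env_matrix()
    lon, lat = raster.cell_centers()
    lon, lat = lon.ravel(), lat.ravel()

    # niche centres: displaced along distinct directions in env space
    dirs = np.zeros((spec.n_ecotypes, spec.n_variables))
    for e in range(spec.n_ecotypes):
        dirs[e, e % spec.n_variables] = 1.0
        if spec.n_ecotypes > spec.n_variables:
            dirs[e] += 0.3 * rng.standard_normal(spec.n_variables)
    # orthogonal unit directions scaled so pairwise centre distance equals
    # niche_separation
    centres = dirs * spec.niche_separation / np.sqrt(2.0)
    centres -= centres.mean(axis=0)

    frames = []
    for e in range(spec.n_ecotypes):
        logw = -0.5 * np.sum((env - centres[e])**2, axis=1) / spec.niche_sd**2
        w = np.exp(logw - logw.max())
        w /= w.sum()
        cells = rng.choice(len(w), size=spec.n_occurrences, replace=True, p=w)
        jitter = (rng.uniform(0, 1, size=(spec.n_occurrences, 2))) * spec.cellsize
        obs_env = env[cells] + spec.noise_sd * rng.standard_normal(
            (spec.n_occurrences, spec.n_variables))
        frames.append(pd.DataFrame({
            "longitude": lon[cells] - spec.cellsize / 2 + jitter[:, 0],
            "latitude": lat[cells] - spec.cellsize / 2 + jitter[:, 1],
            "altitude": 1000.0 + 500.0 * env[cells, 0],
            **{f"env{v + 1}": obs_env[:, v] for v in range(spec.n_variables)},
            "ecotype": e,
        }))
    occ = OccurrenceSet(pd.concat(frames, ignore_index=True))
    return raster, occ
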