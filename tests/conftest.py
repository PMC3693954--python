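import numpy as np
import pytest

from haploniche import HaplotypeTable, HaplotypeDistances, PopulationMeta


@pytest.fixture
def rng():
    return np.random.default_rng(20130626)


@pytest.fixture
def structured_table():
    """Four populations in two clearly differentiated pairs."""
    counts = np.array([
        [12, 3, 1, 0],
        [10, 5, 1, 0],
        [0, 1, 3, 12],
        [1, 0, 5, 10],
    ])
    return HaplotypeTable(counts, ["p1", "p2", "p3", "p4"],
                          ["h1", "h2", "h3", "h4"], genome="mt")


@pytest.fixture
def step_distances():
    """Haplotypes on a path h1-h2-h3-h4, one mutation per link."""
    steps = np.abs(np.subtract.outer(np.arange(4), np.arange(4))).astype(float)
    return HaplotypeDistances(steps, ["h1", "h2", "h3", "h4"],
                              metric_tag="nucleotide_steps")


@pytest.fixture
def square_meta():
    """Six populations: two clusters of three, far apart east-west."""
    coords = [(98.0, 25.0), (98.4, 25.5), (98.2, 24.6),
              (106.0, 25.0), (106.4, 25.5), (106.2, 24.6)]
    return [PopulationMeta(f"p{i + 1}", f"pop{i + 1}", lon, lat, 1500.0,
                           16, 16)
            for i, (lon, lat) in enumerate(coords)]


def random_table(rng, n_pops=6, n_haps=5, n=20, alpha=2.0):
    """Dirichlet-multinomial table that always satisfies the invariants."""
    while True:
        counts = np.stack([
            rng.multinomial(n, rng.dirichlet(np.full(n_haps, alpha / n_haps)))
            for _ in range(n_pops)])
        keep = counts.sum(axis=0) > 0
        counts = counts[:, keep]
        if counts.shape[1] >= 2 and np.all(counts.sum(axis=1) >= 2):
            return HaplotypeTable(counts,
                                  [f"p{i}" for i in range(n_pops)],
                                  [f"h{j}" for j in range(counts.shape[1])])
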