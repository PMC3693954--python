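"""AMOVA variance decomposition and SAMOVA annealing search."""

import itertools

import numpy as np
import networkx as nx
import pytest

from haploniche import (
    HaplotypeTable, HaplotypeDistances, PopulationMeta,
    amova, build_neighbor_graph, samova, scan_K,
)
from haploniche.amova import (
    _one_level_components, _two_level_components, _random_contiguous_partition,
    _is_contiguous, _fct_of,
)
from haploniche.simulate import IslandModelSpec, simulate_haplotype_table

from conftest import random_table


def brute_force_ss(counts, d2):
    """Explicit individual-level sums of squares for every nesting level."""
    hap = np.repeat(np.tile(np.arange(counts.shape[1]), counts.shape[0]),
                    counts.ravel())
    pop = np.repeat(np.arange(counts.shape[0]), counts.sum(axis=1))
    N = len(hap)

    def ss(indices):
        tot = 0.0
        for a in range(len(indices)):
            for b in range(a + 1, len(indices)):
                tot += d2[hap[indices[a]], hap[indices[b]]]
        return tot / len(indices)

    ss_t = ss(np.arange(N))
    ss_w = sum(ss(np.flatnonzero(pop == p)) for p in range(counts.shape[0]))
    return ss_t, ss_w


def test_two_populations_fixed_hand_computation():
    """Two populations fixed for different haplotypes, identity distances,
    n=4 each: SS computed by hand on the 8 individuals."""
    t = HaplotypeTable(np.array([[4, 0], [0, 4]]), ["a", "b"], ["h1", "h2"])
    res = amova(t)
    # 16 cross pairs at squared distance 1: SS_total = 16/8 = 2, SS_within = 0
    assert res.components[0]["SS"] == pytest.approx(2.0, abs=1e-12)
    assert res.components[1]["SS"] == pytest.approx(0.0, abs=1e-12)
    assert res.components[0]["percent"] == pytest.approx(100.0, abs=1e-9)
    assert res.F_statistics["FST"] == pytest.approx(1.0, abs=1e-12)
    assert res.components[0]["df"] + res.components[1]["df"] == 7


def test_identical_populations_no_among_variance():
    t = HaplotypeTable(np.array([[8, 8], [8, 8], [8, 8]]),
                       ["a", "b", "c"], ["h1", "h2"])
    res = amova(t)
    assert res.components[0]["variance"] <= 1e-12
    assert res.components[0]["percent"] <= 1e-9


def test_ss_matches_brute_force_decomposition(rng):
    """AMOVA SS from the count-matrix shortcut equals the explicit
    pairwise-distance computation on expanded individuals (<= 30)."""
    for _ in range(10):
        t = random_table(rng, n_pops=4, n_haps=4, n=7)
        d2 = np.abs(np.subtract.outer(
            np.arange(t.n_haplotypes), np.arange(t.n_haplotypes))).astype(float)
        dist = HaplotypeDistances(d2, t.haplotype_ids)
        res = amova(t, dist)
        ss_t_bf, ss_w_bf = brute_force_ss(t.counts, d2)
        assert res.components[0]["SS"] == pytest.approx(ss_t_bf - ss_w_bf, abs=1e-9)
        assert res.components[1]["SS"] == pytest.approx(ss_w_bf, abs=1e-9)


def test_two_level_ss_matches_brute_force(rng):
    t = random_table(rng, n_pops=6, n_haps=4, n=5)
    d2 = 1.0 - np.eye(t.n_haplotypes)
    grouping = {p: i // 3 for i, p in enumerate(t.population_ids)}
    res = amova(t, HaplotypeDistances(d2, t.haplotype_ids), grouping=grouping)
    ss_t_bf, ss_wp_bf = brute_force_ss(t.counts, d2)
    ss_total = sum(c["SS"] for c in res.components)
    assert ss_total == pytest.approx(ss_t_bf, abs=1e-9)
    assert res.components[2]["SS"] == pytest.approx(ss_wp_bf, abs=1e-9)
    assert sum(c["percent"] for c in res.components) == pytest.approx(100.0, abs=0.01)
    N = t.sample_sizes.sum()
    assert sum(c["df"] for c in res.components) == N - 1


def test_permutation_pvalues_flag_real_structure(structured_table,
                                                 step_distances, rng):
    res = amova(structured_table, step_distances, n_perm=200, rng=rng)
    assert res.p_values["FST"] < 0.05
    flat = HaplotypeTable(np.array([[8, 8], [8, 8], [8, 8], [8, 8]]),
                          ["a", "b", "c", "d"], ["h1", "h2"])
    res2 = amova(flat, n_perm=200, rng=rng)
    assert res2.p_values["FST"] > 0.5


def test_delaunay_neighbor_graph_cases():
    tri = [PopulationMeta(f"p{i}", "x", lon, lat, 0.0)
           for i, (lon, lat) in enumerate([(0, 0), (1, 0), (0.5, 1)])]
    g = build_neighbor_graph(tri)
    assert g.number_of_edges() == 3
    quad = [PopulationMeta(f"p{i}", "x", lon, lat, 0.0)
            for i, (lon, lat) in enumerate([(0, 0), (1, 0), (1, 1), (0, 1)])]
    g = build_neighbor_graph(quad)
    assert g.number_of_edges() == 5  # square: 4 sides + 1 diagonal
    dup = [PopulationMeta(f"p{i}", "x", 0.0, 0.0, 0.0) for i in range(3)]
    with pytest.raises(ValueError, match="duplicate"):
        build_neighbor_graph(dup)


def test_collinear_fallback_connected():
    line = [PopulationMeta(f"p{i}", "x", float(i), 0.0, 0.0) for i in range(5)]
    g = build_neighbor_graph(line)
    assert nx.is_connected(g)


def _two_cluster_table():
    counts = np.array([
        [14, 2, 0, 0], [13, 3, 0, 0], [12, 4, 0, 0],
        [0, 0, 3, 13], [0, 0, 4, 12], [0, 0, 2, 14],
    ])
    return HaplotypeTable(counts, [f"p{i + 1}" for i in range(6)],
                          ["h1", "h2", "h3", "h4"])


def enumerate_best_fct(table, d2, graph, K):
    ids = table.population_ids
    best = (-np.inf, None)
    for assign in itertools.product(range(K), repeat=len(ids)):
        assign = np.array(assign)
        if len(np.unique(assign)) != K:
            continue
        if not _is_contiguous(graph, assign, ids, K):
            continue
        fct = _fct_of(table.counts, d2, assign)
        if fct > best[0]:
            best = (fct, assign)
    return best


def test_samova_matches_enumeration_on_six_populations(square_meta, rng):
    """The annealing search finds the exhaustively-enumerated best
    contiguous partition for K=2 on six populations, across seeds."""
    table = _two_cluster_table()
    d2 = 1.0 - np.eye(4)
    graph = build_neighbor_graph(square_meta)
    best_fct, best_assign = enumerate_best_fct(table, d2, graph, 2)
    hits = 0
    for seed in range(10):
        res = samova(table, None, square_meta, K=2, n_restarts=5, n_iter=150,
                     n_null=0, rng=np.random.default_rng(seed))
        if res.FCT == pytest.approx(best_fct, abs=1e-10):
            hits += 1
    assert hits == 10
    # and the partition is the true east/west split
    groups = [res.partition[f"p{i + 1}"] for i in range(6)]
    assert groups[:3] == [groups[0]] * 3 and groups[3:] == [groups[3]] * 3
    assert groups[0] != groups[3]


def test_samova_fct_is_self_consistent_with_amova(square_meta, rng):
    table = _two_cluster_table()
    res = samova(table, None, square_meta, K=3, n_restarts=3, n_iter=100,
                 n_null=0, rng=rng)
    recomputed = amova(table, grouping=res.partition)
    assert res.FCT == pytest.approx(recomputed.F_statistics["FCT"], abs=1e-10)


def test_samova_partitions_are_contiguous(square_meta, rng):
    table = _two_cluster_table()
    graph = build_neighbor_graph(square_meta)
    for K in (2, 3, 4):
        res = samova(table, None, square_meta, K=K, n_restarts=2, n_iter=80,
                     n_null=0, rng=rng)
        assign = np.array([res.partition[p] for p in table.population_ids])
        assert _is_contiguous(graph, assign, table.population_ids, K)


def test_samova_rejects_bad_K(square_meta, rng):
    table = _two_cluster_table()
    with pytest.raises(ValueError):
        samova(table, None, square_meta, K=1, rng=rng)
    with pytest.raises(ValueError):
        samova(table, None, square_meta, K=6, rng=rng)


def test_random_contiguous_partitions_are_valid(square_meta, rng):
    graph = build_neighbor_graph(square_meta)
    ids = [m.population_id for m in square_meta]
    for _ in range(50):
        assign = _random_contiguous_partition(graph, ids, 3, rng)
        assert len(np.unique(assign)) == 3


def test_scan_K_finds_cluster_count(square_meta, rng):
    """F_CT-by-K scan peaks at the simulated number of clusters."""
    table = _two_cluster_table()
    res = scan_K(table, None, square_meta, K_range=range(2, 5),
                 n_restarts=3, n_iter=120, n_null=0, rng=rng)
    curve = dict(res.FCT_by_K)
    assert res.K == 2 or curve[2] >= max(curve.values()) - 1e-9


def test_flat_data_gives_low_fct_curve(square_meta, rng):
    flat = HaplotypeTable(np.tile([8, 8], (6, 1)),
                          [f"p{i + 1}" for i in range(6)], ["h1", "h2"])
    res = scan_K(flat, None, square_meta, K_range=range(2, 4),
                 n_restarts=2, n_iter=60, n_null=0, rng=rng)
    assert all(f < 0.1 for _, f in res.FCT_by_K)
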