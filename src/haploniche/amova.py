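"""AMOVA variance decomposition and the SAMOVA spatial partition search.

AMOVA follows the Excoffier molecular-variance framework on haploid
individuals expanded from haplotype counts: sums of squares are computed
from squared inter-haplotype distances (the distance matrix entries are
treated as squared distances, so mutation-step counts plug in directly,
as in the classic implementation), variance components from the nested
mean squares, and F-statistics are tested by the standard permutation
schemes (individuals among populations for F_ST, populations among
groups for F_CT, individuals among populations within groups for F_SC).

SAMOVA searches, by simulated annealing over spatially contiguous
partitions of the population neighbour graph, for the K-group partition
maximizing the among-group fixation index F_CT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import networkx as nx
from scipy.spatial import Delaunay, QhullError

from .config import PopulationMeta
from .haplostats import HaplotypeTable, HaplotypeDistances


@dataclass
class AmovaResult:
    """Variance components with d.f., SS, percentages, F-statistics and
    permutation p-values."""

    components: list[dict]          # name, df, SS, variance, percent
    F_statistics: dict[str, float]  # FST always; FSC/FCT when grouped
    p_values: dict[str, float] = field(default_factory=dict)

    @property
    def percentages(self) -> dict[str, float]:
        return {c["name"]: c["percent"] for c in self.components}


@dataclass
class SamovaResult:
    K: int
    partition: dict[str, int]
    FCT: float
    p_value: float | None = None
    n_restarts: int = 0
    FCT_by_K: list[tuple[int, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sums of squares from count matrices
#
# For individuals expanded from counts c (length = n haplotypes) the sum of
# squared distances over unordered pairs is c' D c / 2 (diagonal zero), and
# the SS of the unit is that divided by the unit's sample size.

def _ss_unit(count_vec: np.ndarray, d2: np.ndarray) -> float:
    n = count_vec.sum()
    return float(count_vec @ d2 @ count_vec / (2.0 * n))


def _one_level_components(counts: np.ndarray, d2: np.ndarray) -> tuple[float, float, dict]:
    """(sigma_a, sigma_w, details) for populations with no grouping."""
    P = counts.shape[0]
    n_p = counts.sum(axis=1).astype(float)
    N = n_p.sum()
    ss_t = _ss_unit(counts.sum(axis=0), d2)
    ss_w = sum(_ss_unit(counts[i], d2) for i in range(P))
    ss_a = ss_t - ss_w
    df_a, df_w = P - 1, N - P
    ms_a, ms_w = ss_a / df_a, ss_w / df_w
    n_prime = (N - np.sum(n_p**2) / N) / (P - 1)
    sigma_w = ms_w
    sigma_a = (ms_a - ms_w) / n_prime
    return sigma_a, sigma_w, dict(ss_t=ss_t, ss_w=ss_w, ss_a=ss_a,
                                  df_a=df_a, df_w=df_w)


def _two_level_components(counts: np.ndarray, d2: np.ndarray,
                          groups: np.ndarray) -> tuple[float, float, float, dict]:
    """(sigma_a, sigma_b, sigma_w, details) for populations nested in groups."""
    P = counts.shape[0]
    n_p = counts.sum(axis=1).astype(float)
    N = n_p.sum()
    glabels = np.unique(groups)
    G = len(glabels)
    ss_t = _ss_unit(counts.sum(axis=0), d2)
    ss_wp = sum(_ss_unit(counts[i], d2) for i in range(P))
    ss_wg = 0.0
    Ng = np.empty(G)
    sum_np2_g = np.empty(G)
    for gi, g in enumerate(glabels):
        members = groups == g
        ss_wg += _ss_unit(counts[members].sum(axis=0), d2)
        Ng[gi] = n_p[members].sum()
        sum_np2_g[gi] = np.sum(n_p[members] ** 2)
    ss_ag = ss_t - ss_wg
    ss_ap = ss_wg - ss_wp
    df_ag, df_ap, df_wp = G - 1, P - G, N - P
    ms_wp = ss_wp / df_wp
    ms_ap = ss_ap / df_ap if df_ap > 0 else ms_wp
    ms_ag = ss_ag / df_ag
    n1 = (N - np.sum(sum_np2_g / Ng)) / (P - G) if P > G else 1.0
    n2 = (np.sum(sum_np2_g / Ng) - np.sum(n_p**2) / N) / (G - 1)
    n3 = (N - np.sum(Ng**2) / N) / (G - 1)
    sigma_w = ms_wp
    sigma_b = (ms_ap - ms_wp) / n1 if P > G else 0.0
    sigma_a = (ms_ag - sigma_w - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_w, dict(
        ss_t=ss_t, ss_wp=ss_wp, ss_ap=ss_ap, ss_ag=ss_ag,
        df_ag=df_ag, df_ap=df_ap, df_wp=df_wp)


def _expand_individuals(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(haplotype index, population index) per individual."""
    P, H = counts.shape
    hap = np.repeat(np.tile(np.arange(H), P), counts.ravel())
    pop = np.repeat(np.arange(P), counts.sum(axis=1))
    return hap, pop


def _counts_from_individuals(hap: np.ndarray, pop: np.ndarray, P: int, H: int) -> np.ndarray:
    out = np.zeros((P, H), dtype=np.int64)
    np.add.at(out, (pop, hap), 1)
    return out


def amova(table: HaplotypeTable, dist: HaplotypeDistances | None = None,
          grouping: dict[str, int] | None = None, n_perm: int = 0,
          rng: np.random.Generator | None = None) -> AmovaResult:
    """AMOVA on a haplotype count table.

    grouping maps population id -> group label; omit it for the one-level
    (among/within populations) analysis. n_perm = 0 skips the permutation
    tests. Negative variance components are retained (percentages can be
    slightly negative for unstructured data).
    """
    d2 = (dist.aligned_to(table) if dist is not None
          else HaplotypeDistances.identity(table.haplotype_ids).matrix)
    counts = table.counts
    P, H = counts.shape
    rng = rng or np.random.default_rng()

    if grouping is None:
        sigma_a, sigma_w, det = _one_level_components(counts, d2)
        total = sigma_a + sigma_w
        fst = sigma_a / total if total > 0 else 0.0
        comps = [
            dict(name="among_populations", df=int(det["df_a"]), SS=det["ss_a"],
                 variance=sigma_a, percent=100 * sigma_a / total),
            dict(name="within_populations", df=int(det["df_w"]), SS=det["ss_w"],
                 variance=sigma_w, percent=100 * sigma_w / total),
        ]
        res = AmovaResult(comps, {"FST": float(fst)})
        if n_perm > 0:
            hap, pop = _expand_individuals(counts)
            hits = 0
            for _ in range(n_perm):
                sh = rng.permutation(hap)
                c = _counts_from_individuals(sh, pop, P, H)
                sa, sw, _ = _one_level_components(c, d2)
                t = sa + sw
                if (sa / t if t > 0 else 0.0) >= fst - 1e-12:
                    hits += 1
            res.p_values["FST"] = (hits + 1) / (n_perm + 1)
        return res

    groups = np.array([grouping[p] for p in table.population_ids])
    glabels, gcounts = np.unique(groups, return_counts=True)
    if len(glabels) < 2:
        raise ValueError("grouping must define >= 2 groups")
    if np.any(gcounts < 1):
        raise ValueError("empty group in grouping")
    sigma_a, sigma_b, sigma_w, det = _two_level_components(counts, d2, groups)
    total = sigma_a + sigma_b + sigma_w
    fct = sigma_a / total if total > 0 else 0.0
    fsc = sigma_b / (sigma_b + sigma_w) if (sigma_b + sigma_w) > 0 else 0.0
    fst = (sigma_a + sigma_b) / total if total > 0 else 0.0
    comps = [
        dict(name="among_groups", df=int(det["df_ag"]), SS=det["ss_ag"],
             variance=sigma_a, percent=100 * sigma_a / total),
        dict(name="among_populations_within_groups", df=int(det["df_ap"]),
             SS=det["ss_ap"], variance=sigma_b, percent=100 * sigma_b / total),
        dict(name="within_populations", df=int(det["df_wp"]), SS=det["ss_wp"],
             variance=sigma_w, percent=100 * sigma_w / total),
    ]
    res = AmovaResult(comps, {"FST": float(fst), "FSC": float(fsc), "FCT": float(fct)})
    if n_perm > 0:
        # FCT: permute whole populations among groups
        hits = 0
        for _ in range(n_perm):
            g = rng.permutation(groups)
            sa, sb, sw, _ = _two_level_components(counts, d2, g)
            t = sa + sb + sw
            if (sa / t if t > 0 else 0.0) >= fct - 1e-12:
                hits += 1
        res.p_values["FCT"] = (hits + 1) / (n_perm + 1)
        # FSC: permute individuals among populations within groups
        hap, pop = _expand_individuals(counts)
        hits = 0
        for _ in range(n_perm):
            sh = hap.copy()
            for g in glabels:
                mask = np.isin(pop, np.flatnonzero(groups == g))
                sh[mask] = rng.permutation(sh[mask])
            c = _counts_from_individuals(sh, pop, P, H)
            sa, sb, sw, _ = _two_level_components(c, d2, groups)
            f = sb / (sb + sw) if (sb + sw) > 0 else 0.0
            if f >= fsc - 1e-12:
                hits += 1
        res.p_values["FSC"] = (hits + 1) / (n_perm + 1)
        # FST: permute individuals among populations
        hits = 0
        for _ in range(n_perm):
            sh = rng.permutation(hap)
            c = _counts_from_individuals(sh, pop, P, H)
            sa, sb, sw, _ = _two_level_components(c, d2, groups)
            t = sa + sb + sw
            if ((sa + sb) / t if t > 0 else 0.0) >= fst - 1e-12:
                hits += 1
        res.p_values["FST"] = (hits + 1) / (n_perm + 1)
    return res


# ---------------------------------------------------------------------------
# SAMOVA

def build_neighbor_graph(meta: list[PopulationMeta]) -> nx.Graph:
    """Delaunay neighbour graph on (longitude, latitude).

    Degenerate (collinear) configurations fall back to a 2-nearest-neighbour
    graph augmented to connectivity. Duplicate coordinates are an error.
    """
    if len(meta) < 3:
        raise ValueError("need >= 3 populations for a neighbour graph")
    pts = np.array([[m.longitude, m.latitude] for m in meta])
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate population coordinates")
    G = nx.Graph()
    G.add_nodes_from(m.population_id for m in meta)
    ids = [m.population_id for m in meta]
    try:
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            for a in range(3):
                for b in range(a + 1, 3):
                    G.add_edge(ids[simplex[a]], ids[simplex[b]])
    except QhullError:
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        for i in range(len(pts)):
            for j in np.argsort(d[i])[:2]:
                G.add_edge(ids[i], ids[int(j)])
        while not nx.is_connected(G):
            comps = list(nx.connected_components(G))
            best = (np.inf, None)
            for a in comps[0]:
                for comp in comps[1:]:
                    for b in comp:
                        dd = d[ids.index(a), ids.index(b)]
                        if dd < best[0]:
                            best = (dd, (a, b))
            G.add_edge(*best[1])
    return G


def _is_contiguous(graph: nx.Graph, assign: np.ndarray, ids: list[str], K: int) -> bool:
    for g in range(K):
        members = [ids[i] for i in np.flatnonzero(assign == g)]
        if not members:
            return False
        if not nx.is_connected(graph.subgraph(members)):
            return False
    return True


def _random_contiguous_partition(graph: nx.Graph, ids: list[str], K: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Grow K regions from random seeds by randomized BFS."""
    n = len(ids)
    index = {p: i for i, p in enumerate(ids)}
    assign = np.full(n, -1)
    seeds = rng.choice(n, size=K, replace=False)
    frontier: list[list[int]] = [[int(s)] for s in seeds]
    for g, s in enumerate(seeds):
        assign[s] = g
    while np.any(assign == -1):
        order = rng.permutation(K)
        progressed = False
        for g in order:
            candidates = [index[nb]
                          for node in frontier[g]
                          for nb in graph.neighbors(ids[node])
                          if assign[index[nb]] == -1]
            if candidates:
                pick = int(rng.choice(candidates))
                assign[pick] = g
                frontier[g].append(pick)
                progressed = True
        if not progressed:  # disconnected leftovers: attach to nearest group
            for i in np.flatnonzero(assign == -1):
                nb_groups = [assign[index[nb]] for nb in graph.neighbors(ids[i])
                             if assign[index[nb]] >= 0]
                assign[i] = nb_groups[0] if nb_groups else int(rng.integers(K))
    return assign


def _fct_of(counts: np.ndarray, d2: np.ndarray, assign: np.ndarray) -> float:
    sa, sb, sw, _ = _two_level_components(counts, d2, assign)
    total = sa + sb + sw
    return sa / total if total > 0 else 0.0


def samova(table: HaplotypeTable, dist: HaplotypeDistances | None,
           meta: list[PopulationMeta], K: int,
           n_restarts: int = 100, n_iter: int = 1000,
           cooling: float = 0.95, n_null: int = 100,
           rng: np.random.Generator | None = None,
           graph: nx.Graph | None = None) -> SamovaResult:
    """Simulated-annealing search for the contiguous K-partition maximizing F_CT.

    Each restart grows a random contiguous partition and anneals it by
    single-population border moves (contiguity preserved), Metropolis
    acceptance and geometric cooling. The p-value is the fraction of
    random contiguous partitions with F_CT >= the best found.
    Ties are broken toward the lexicographically smallest label vector.
    """
    P = table.n_populations
    if not 2 <= K <= P - 1:
        raise ValueError(f"K={K} outside [2, {P - 1}]")
    rng = rng or np.random.default_rng()
    ids = table.population_ids
    graph = graph if graph is not None else build_neighbor_graph(meta)
    d2 = (dist.aligned_to(table) if dist is not None
          else HaplotypeDistances.identity(table.haplotype_ids).matrix)
    counts = table.counts
    index = {p: i for i, p in enumerate(ids)}

    def canonical(assign: np.ndarray) -> np.ndarray:
        # relabel groups by first occurrence for reproducible tie-breaking
        mapping, nxt = {}, 0
        out = np.empty_like(assign)
        for i, g in enumerate(assign):
            if g not in mapping:
                mapping[g] = nxt
                nxt += 1
            out[i] = mapping[g]
        return out

    best_assign, best_fct = None, -np.inf
    # initial temperature from the spread of F_CT over random partitions
    probe = [_fct_of(counts, d2, _random_contiguous_partition(graph, ids, K, rng))
             for _ in range(10)]
    T0 = max(np.std(probe), 1e-3)

    for _ in range(n_restarts):
        assign = _random_contiguous_partition(graph, ids, K, rng)
        fct = _fct_of(counts, d2, assign)
        cur_best, cur_best_f = assign.copy(), fct
        T = T0
        for _ in range(n_iter):
            # propose moving one border population to a neighbouring group
            moves = []
            for i in range(P):
                src = assign[i]
                if np.sum(assign == src) == 1:
                    continue
                nb_groups = {assign[index[nb]] for nb in graph.neighbors(ids[i])}
                nb_groups.discard(src)
                for g in nb_groups:
                    moves.append((i, g))
            if not moves:
                break
            i, g = moves[int(rng.integers(len(moves)))]
            trial = assign.copy()
            trial[i] = g
            if not _is_contiguous(graph, trial, ids, K):
                T *= cooling
                continue
            f_new = _fct_of(counts, d2, trial)
            delta = f_new - fct
            if delta > 0 or rng.random() < np.exp(delta / max(T, 1e-12)):
                assign, fct = trial, f_new
                if fct > cur_best_f:
                    cur_best, cur_best_f = assign.copy(), fct
            T *= cooling
        ca = canonical(cur_best)
        if cur_best_f > best_fct + 1e-12 or (
                abs(cur_best_f - best_fct) <= 1e-12 and best_assign is not None
                and tuple(ca) < tuple(best_assign)):
            best_assign, best_fct = ca, cur_best_f

    p_value = None
    if n_null > 0:
        hits = sum(
            _fct_of(counts, d2, _random_contiguous_partition(graph, ids, K, rng))
            >= best_fct - 1e-12
            for _ in range(n_null))
        p_value = (hits + 1) / (n_null + 1)
    return SamovaResult(K=K, partition=dict(zip(ids, map(int, best_assign))),
                        FCT=float(best_fct), p_value=p_value,
                        n_restarts=n_restarts)


def scan_K(table: HaplotypeTable, dist: HaplotypeDistances | None,
           meta: list[PopulationMeta], K_range=range(2, 11),
           rng: np.random.Generator | None = None, **kwargs) -> SamovaResult:
    """Run samova over a range of K; return the argmax result with the
    full F_CT-by-K curve attached."""
    rng = rng or np.random.default_rng()
    graph = build_neighbor_graph(meta)
    curve, results = [], []
    for K in K_range:
        res = samova(table, dist, meta, K, rng=rng, graph=graph, **kwargs)
        curve.append((K, res.FCT))
        results.append(res)
    best = max(results, key=lambda r: r.FCT)
    best.FCT_by_K = curve
    return best
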