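"""Median-joining haplotype networks.

Builds Bandelt-style median-joining networks from aligned organellar
sequences or cpSSR haplotypes. Complex indel regions (a hallmark of
plant mitochondrial alignments) can be declared as blocks; each block is
collapsed to a single multistate character whose states are the distinct
block sequences, all at mutual distance one — treating distinct block
types as products of independent insertion events, which yields the most
compact network. Remaining variable columns become ordinary site
characters, so the inter-haplotype distance is a unit-step Hamming
distance on the recoded matrix.

The network construction iterates: build the epsilon-relaxed minimum
spanning network over the current node set; for every connected triple,
propose its quasi-median (per-character majority state; ties branch);
keep any median that strictly shortens the minimum spanning tree of the
node set; stop at a fixed point. Because Hamming distance is a metric, a
median can only be retained where it attains degree >= 3.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import networkx as nx

from .haplostats import HaplotypeTable, HaplotypeDistances

_VALID = set("ACGTRYSWKMBDHVN-")


@dataclass
class SequenceSet:
    """Equal-length aligned sequences with optional declared indel blocks.

    indel_blocks are half-open (start, end) column ranges to be recoded
    as single multistate characters; they must not overlap.
    """

    names: list[str]
    sequences: list[str]
    indel_blocks: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequences:
            raise ValueError("empty sequence set")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("sequences have unequal lengths (not an alignment)")
        if len(self.names) != len(self.sequences):
            raise ValueError("names/sequences length mismatch")
        self.sequences = [s.upper() for s in self.sequences]
        for s, name in zip(self.sequences, self.names):
            bad = set(s) - _VALID
            if bad:
                raise ValueError(f"{name}: invalid letters {sorted(bad)}")
        blocks = sorted(self.indel_blocks)
        for (a, b) in blocks:
            if not (0 <= a < b <= L):
                raise ValueError(f"indel block ({a}, {b}) out of bounds")
        for (a, b), (c, d) in zip(blocks, blocks[1:]):
            if c < b:
                raise ValueError("overlapping indel blocks")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class CharacterMatrix:
    """Haplotypes x characters state matrix; every character is unit-step
    (distance 1 between any two distinct states), so inter-haplotype
    distance is the Hamming distance between rows."""

    states: np.ndarray  # int codes, shape (n_haplotypes, n_characters)
    names: list[str]
    character_labels: list[str]

    def hamming(self) -> np.ndarray:
        s = self.states
        return (s[:, None, :] != s[None, :, :]).sum(axis=2)


def recode_characters(seqs: SequenceSet) -> CharacterMatrix:
    """Collapse declared indel blocks to single multistate characters and
    the remaining variable columns to site characters; invariant columns
    are dropped."""
    n = len(seqs)
    cols: list[np.ndarray] = []
    labels: list[str] = []
    in_block = np.zeros(seqs.length, dtype=bool)
    for (a, b) in seqs.indel_blocks:
        in_block[a:b] = True
        block = [s[a:b] for s in seqs.sequences]
        for bs, name in zip(block, seqs.names):
            amb = set(bs) - set("ACGT-")
            if amb:
                raise ValueError(
                    f"{name}: ambiguous letters {sorted(amb)} inside indel block ({a}, {b})")
        state_of: dict[str, int] = {}
        codes = np.empty(n, dtype=np.int64)
        for i, bs in enumerate(block):
            codes[i] = state_of.setdefault(bs, len(state_of))
        if len(state_of) > 1:
            cols.append(codes)
            labels.append(f"indel_{a}_{b}")
    for j in range(seqs.length):
        if in_block[j]:
            continue
        letters = [s[j] for s in seqs.sequences]
        if len(set(letters)) > 1:
            state_of = {}
            codes = np.array([state_of.setdefault(c, len(state_of)) for c in letters])
            cols.append(codes)
            labels.append(f"site_{j}")
    states = (np.stack(cols, axis=1) if cols
              else np.zeros((n, 0), dtype=np.int64))
    return CharacterMatrix(states=states, names=list(seqs.names),
                           character_labels=labels)


def _mst_weight(nodes: np.ndarray) -> int:
    """Exact MST weight under Hamming distance (Prim's algorithm)."""
    m = nodes.shape[0]
    if m < 2:
        return 0
    d = (nodes[:, None, :] != nodes[None, :, :]).sum(axis=2)
    in_tree = np.zeros(m, dtype=bool)
    in_tree[0] = True
    key = d[0].copy()
    total = 0
    for _ in range(m - 1):
        key_masked = np.where(in_tree, np.iinfo(np.int64).max, key)
        j = int(np.argmin(key_masked))
        total += int(key_masked[j])
        in_tree[j] = True
        key = np.minimum(key, d[j])
    return total


def _msn_edges(nodes: np.ndarray, epsilon: int = 0) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum spanning network.

    Edges are processed by ascending weight class; an edge joins the
    network if its endpoints lie in different components of the graph of
    strictly lighter classes (minus epsilon relaxation). With epsilon=0
    this is the union of all minimum spanning trees.
    """
    m = nodes.shape[0]
    d = (nodes[:, None, :] != nodes[None, :, :]).sum(axis=2)
    pairs = [(int(d[i, j]), i, j) for i in range(m) for j in range(i + 1, m)]
    pairs.sort()
    parent = list(range(m))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    edges = []
    weights = sorted({w for w, _, _ in pairs})
    by_weight = {w: [(i, j) for ww, i, j in pairs if ww == w] for w in weights}
    unioned: set[int] = set()
    for w in weights:
        # eligibility at weight w is judged on components of classes < w - epsilon
        for wj in weights:
            if wj < w - epsilon and wj not in unioned:
                for i, j in by_weight[wj]:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
                unioned.add(wj)
        eligible = [(i, j) for i, j in by_weight[w] if find(i) != find(j)]
        edges.extend((i, j, w) for i, j in eligible)
    return edges


def _quasi_medians(u: np.ndarray, v: np.ndarray, w: np.ndarray,
                   max_tie_chars: int = 6) -> list[np.ndarray]:
    """Per-character majority state of a triple; full ties branch into all
    three states (capped to avoid combinatorial explosion)."""
    base = u.copy()
    tie_positions = []
    for j in range(len(u)):
        trio = (u[j], v[j], w[j])
        vals, cnts = np.unique(trio, return_counts=True)
        if cnts.max() >= 2:
            base[j] = vals[np.argmax(cnts)]
        else:
            tie_positions.append(j)
    if not tie_positions:
        return [base]
    tie_positions = tie_positions[:max_tie_chars]
    out = []
    for combo in itertools.product(*[(u[j], v[j], w[j]) for j in tie_positions]):
        cand = base.copy()
        for j, s in zip(tie_positions, combo):
            cand[j] = s
        out.append(cand)
    return out


def median_joining(matrix: CharacterMatrix,
                   frequencies: dict[str, int] | None = None,
                   epsilon: int = 0,
                   outgroup: set[str] | None = None) -> nx.Graph:
    """Median-joining network over the haplotypes of a character matrix.

    Returns a networkx Graph whose nodes carry label, frequency,
    observed and outgroup attributes, and whose edges carry the
    mutation-step count ('steps').
    """
    rows = matrix.states
    uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
    label_of: dict[int, list[str]] = {}
    for i, name in enumerate(matrix.names):
        label_of.setdefault(int(inverse[i]), []).append(name)
    if uniq.shape[0] < 2:
        raise ValueError("need >= 2 distinct haplotypes")

    nodes = [uniq[i] for i in range(uniq.shape[0])]
    observed = [True] * len(nodes)

    changed = True
    while changed:
        changed = False
        arr = np.stack(nodes)
        base_weight = _mst_weight(arr)
        edges = _msn_edges(arr, epsilon=epsilon)
        adj: dict[int, set[int]] = {i: set() for i in range(len(nodes))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        seen = {tuple(x) for x in nodes}
        for b in range(len(nodes)):
            for a, c in itertools.combinations(sorted(adj[b]), 2):
                for med in _quasi_medians(nodes[a], nodes[b], nodes[c]):
                    key = tuple(med)
                    if key in seen:
                        continue
                    trial = np.vstack([arr, med])
                    if _mst_weight(trial) < base_weight:
                        nodes.append(med)
                        observed.append(False)
                        seen.add(key)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break

    # drop medians made redundant by later additions
    pruned = True
    while pruned:
        pruned = False
        arr = np.stack(nodes)
        w_all = _mst_weight(arr)
        for i in range(len(nodes)):
            if observed[i]:
                continue
            rest = np.delete(arr, i, axis=0)
            if _mst_weight(rest) == w_all:
                del nodes[i]
                del observed[i]
                pruned = True
                break

    arr = np.stack(nodes)
    edges = _msn_edges(arr, epsilon=epsilon)
    G = nx.Graph()
    med_counter = 0
    node_names = []
    for i, vec in enumerate(nodes):
        if observed[i]:
            orig = label_of[next(k for k in label_of
                                 if tuple(uniq[k]) == tuple(vec))]
            name = orig[0]
            freq = sum((frequencies or {}).get(nm, 1) for nm in orig)
        else:
            med_counter += 1
            name = f"mv{med_counter}"
            freq = 0
        node_names.append(name)
        G.add_node(name, observed=bool(observed[i]), frequency=int(freq),
                   members=",".join(label_of.get(
                       next((k for k in label_of if tuple(uniq[k]) == tuple(vec)), -1), [])),
                   outgroup=bool(outgroup and name in outgroup))
    for i, j, w in edges:
        G.add_edge(node_names[i], node_names[j], steps=int(w))
    return G


def exclude_singletons(table: HaplotypeTable) -> tuple[HaplotypeTable, list[str]]:
    """Drop haplotypes whose total count over all populations is 1.

    Returns the filtered table and the removed haplotype labels.
    """
    totals = table.pooled_counts()
    keep = totals > 1
    removed = [h for h, k in zip(table.haplotype_ids, keep) if not k]
    if not keep.any():
        raise ValueError("all haplotypes are singletons; nothing to analyse")
    if keep.all():
        return table, []
    rows_keep = table.counts[:, keep].sum(axis=1) > 0
    return HaplotypeTable(
        table.counts[np.ix_(rows_keep, keep)],
        [p for p, k in zip(table.population_ids, rows_keep) if k],
        [h for h, k in zip(table.haplotype_ids, keep) if k],
        genome=table.genome), removed


def cpssr_steps(genotypes: np.ndarray, haplotype_ids: list[str] | None = None,
                motif_length: int = 1, squared: bool = False) -> HaplotypeDistances:
    """Inter-chlorotype distances from 5-locus (or any-locus) allele sizes.

    Fragment sizes are converted to repeat counts assuming the given motif
    length (cpSSR loci are mononucleotide by default). The stepwise
    distance sums |repeat difference| across loci; squared=True gives the
    summed squared differences used by R_ST.
    """
    g = np.asarray(genotypes, dtype=float)
    if g.ndim != 2:
        raise ValueError("genotypes must be haplotypes x loci")
    if np.any(~np.isfinite(g)):
        raise ValueError("missing allele sizes")
    if np.any(g <= 0):
        raise ValueError("allele sizes must be positive")
    reps = g / motif_length
    offsets = reps - reps.min(axis=0)
    if np.any(np.abs(offsets - np.round(offsets)) > 1e-6):
        raise ValueError("allele size differences are not multiples of the motif length")
    diff = reps[:, None, :] - reps[None, :, :]
    if squared:
        mat = np.sum(diff**2, axis=2)
        tag = "squared_repeat"
    else:
        mat = np.sum(np.abs(diff), axis=2)
        tag = "stepwise"
    ids = haplotype_ids or [f"C{i + 1}" for i in range(g.shape[0])]
    return HaplotypeDistances(mat, ids, metric_tag=tag)
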