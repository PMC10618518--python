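"""Independent brute-force oracles used across the test suite.

Everything here recomputes quantities from first principles (exhaustive
enumeration, direct definitions) so it stays independent of the library
code paths it checks.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
from sympy.utilities.iterables import multiset_partitions


def brute_force_average_linkage(d0: np.ndarray):
    """Naive UPGMA: recompute every cluster distance as the mean over all
    cross-pair leaf distances at every step (no Lance-Williams update).

    Ties on the minimum distance break toward the pair with the
    lexicographically smallest (min-leaf, min-leaf) indices. Returns the
    list of merge heights in merge order.
    """
    n = d0.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = float(np.mean([d0[i, j] for i in a for j in b]))
            key = (avg, min(min(a), min(b)), max(min(a), min(b)))
            if best is None or key < best[0]:
                best = (key, a, b)
        key, a, b = best
        heights.append(key[0])
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights


def modularity_of(adj: np.ndarray, blocks, resolution: float = 1.0) -> float:
    """Newman modularity of a node partition, straight from the definition."""
    m2 = adj.sum()  # = 2m
    if m2 == 0:
        return 0.0
    k = adj.sum(axis=1)
    q = 0.0
    for block in blocks:
        idx = np.array(sorted(block))
        q += adj[np.ix_(idx, idx)].sum() / m2
        q -= resolution * (k[idx].sum() / m2) ** 2
    return q


def brute_force_max_modularity(g: nx.Graph, resolution: float = 1.0):
    """Exhaustive maximum modularity over all partitions of the nodes.

    Feasible up to ~10 nodes (Bell(8) = 4140 partitions). Returns
    (best_modularity, best_partition_as_list_of_sets).
    """
    nodes = sorted(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)))
    for u, v in g.edges:
        adj[index[u], index[v]] += 1
        adj[index[v], index[u]] += 1
    best_q, best_p = -np.inf, None
    for part in multiset_partitions(list(range(len(nodes)))):
        q = modularity_of(adj, part, resolution)
        if q > best_q:
            best_q, best_p = q, part
    blocks = [{nodes[i] for i in block} for block in best_p]
    return best_q, blocks


def venn_regions_brute(sets: dict[str, set]) -> dict[frozenset, int]:
    """Region cardinalities by brute-force membership of every element."""
    universe = set().union(*sets.values())
    regions: dict[frozenset, int] = {}
    for x in universe:
        key = frozenset(g for g, s in sets.items() if x in s)
        regions[key] = regions.get(key, 0) + 1
    return regions
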