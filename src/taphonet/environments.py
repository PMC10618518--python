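"""Sedimentary-environment inference from aquatic-taxon abundances.

Plots are compared by the Bray-Curtis dissimilarity of their aquatic
OTU counts, d(u, v) = sum_i |u_i - v_i| / sum_i (u_i + v_i), and grouped
by average-linkage (UPGMA) agglomeration: the distance between two
clusters is the mean over all cross-pair leaf distances. Cutting the
tree at k groups partitions the plots into candidate depositional
environments (e.g. shoal / bay / shallow lake); Venn summaries and
cluster-ordered heatmap tables describe the taxa shared between them.

The agglomeration is implemented directly (plots number in the dozens
at most) so that ties in the minimum inter-cluster distance break
deterministically toward the lexicographically smallest pair, and so
that any height inversion — possible in principle for average linkage
on a non-metric dissimilarity — is detected and reported rather than
hidden.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sample_io import AbundanceMatrix, SpecimenTable

__all__ = [
    "DistanceMatrix",
    "Dendrogram",
    "VennSummary",
    "bray_curtis",
    "distance_matrix",
    "cluster_plots",
    "cut_clusters",
    "venn",
    "heatmap_table",
]


def bray_curtis(u: Sequence[float], v: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity between two nonnegative abundance vectors.

    Bounded in [0, 1]; 0 for identical vectors, 1 for disjoint support.
    Undefined (error) when both vectors are entirely zero.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have the same length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be nonnegative")
    denom = float(np.sum(u + v))
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two all-zero vectors")
    return float(np.sum(np.abs(u - v)) / denom)


@dataclass
class DistanceMatrix:
    """Symmetric plot-by-plot dissimilarities with zero diagonal."""

    items: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.items), len(self.items)):
            raise ValueError("distance matrix shape does not match items")
        if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.d = d

    def between(self, a: str, b: str) -> float:
        i, j = self.items.index(a), self.items.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.items, columns=self.items)


def distance_matrix(matrix: AbundanceMatrix, *, relative: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis distances between plots (matrix columns).

    With ``relative=True`` each plot's counts are first normalised to
    proportions, comparing composition rather than raw abundance.
    """
    data = matrix.counts.to_numpy(dtype=float).T  # plots x taxa
    if relative:
        totals = data.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("cannot use relative abundances with an all-zero plot")
        data = data / totals
    n = data.shape[0]
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = bray_curtis(data[i], data[j])
    return DistanceMatrix(items=list(matrix.plots), d=d)


@dataclass
class Dendrogram:
    """Binary agglomeration tree over named leaves.

    ``merges`` lists, in merge order, tuples ``(left, right, height,
    size)`` where left/right are node ids (leaves are 0..n-1, the i-th
    merge creates node n+i) and height is the average-linkage distance
    at which the two clusters joined. ``inversions`` records merges
    whose height dropped below the preceding merge's height.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, int]]
    inversions: list[int] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def _children(self) -> dict[int, tuple[int, int]]:
        n = self.n_leaves
        return {n + i: (m[0], m[1]) for i, m in enumerate(self.merges)}

    def leaf_order(self) -> list[str]:
        """Left-to-right leaf order of the tree (for heatmap axes)."""
        if not self.merges:
            return list(self.leaves)
        children = self._children()
        root = self.n_leaves + len(self.merges) - 1
        out: list[str] = []

        def walk(node: int) -> None:
            if node < self.n_leaves:
                out.append(self.leaves[node])
            else:
                left, right = children[node]
                walk(left)
                walk(right)

        walk(root)
        return out

    def to_newick(self) -> str:
        """Newick string; branch lengths are height differences."""
        children = self._children()
        heights = {i: 0.0 for i in range(self.n_leaves)}
        for i, (_, _, h, _) in enumerate(self.merges):
            heights[self.n_leaves + i] = h
        root = self.n_leaves + len(self.merges) - 1 if self.merges else 0

        def fmt(node: int, parent_h: float) -> str:
            bl = max(parent_h - heights[node], 0.0)
            if node < self.n_leaves:
                return f"{self.leaves[node]}:{bl:g}"
            left, right = children[node]
            h = heights[node]
            return f"({fmt(left, h)},{fmt(right, h)}):{bl:g}"

        if not self.merges:
            return f"{self.leaves[0]};"
        h_root = heights[root]
        left, right = children[root]
        return f"({fmt(left, h_root)},{fmt(right, h_root)});"


def _upgma(items: list[str], d0: np.ndarray) -> Dendrogram:
    """Naive average-linkage agglomeration with lexicographic tie-breaks.

    Cluster-to-cluster distance is maintained exactly as the mean of all
    cross-pair leaf distances (Lance-Williams update with size weights).
    """
    n = len(items)
    # active cluster id -> (node id, leaf count)
    active: dict[int, tuple[int, int]] = {i: (i, 1) for i in range(n)}
    dist: dict[frozenset[int], float] = {
        frozenset((i, j)): float(d0[i, j])
        for i, j in itertools.combinations(range(n), 2)
    }
    merges: list[tuple[int, int, float, int]] = []
    inversions: list[int] = []
    next_node = n
    last_h = -np.inf
    while len(active) > 1:
        # minimal distance; ties -> smallest (i, j) with i < j
        best = min(
            ((min(k), max(k), v) for k, v in dist.items()),
            key=lambda t: (t[2], t[0], t[1]),
        )
        i, j, h = best
        ni, si = active[i]
        nj, sj = active[j]
        if h < last_h - 1e-12:
            inversions.append(len(merges))
        last_h = h
        merges.append((ni, nj, h, si + sj))
        # average-linkage update against every other active cluster
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist.pop(frozenset((i, k)))
            djk = dist.pop(frozenset((j, k)))
            dist[frozenset((i, k))] = (si * dik + sj * djk) / (si + sj)
        del dist[frozenset((i, j))]
        del active[j]
        active[i] = (next_node, si + sj)
        next_node += 1
    return Dendrogram(leaves=list(items), merges=merges, inversions=inversions)


def cluster_plots(
    matrix: AbundanceMatrix,
    *,
    relative: bool = False,
) -> Dendrogram:
    """Average-linkage clustering of plots by Bray-Curtis distance.

    The caller is expected to have restricted the matrix to the taxa of
    interest first (typically aquatic OTUs with pooled abundance > 5,
    via :func:`taphonet.sample_io.filter_min_total`).
    """
    if len(matrix.plots) < 2:
        raise ValueError("need at least two plots to cluster")
    dm = distance_matrix(matrix, relative=relative)
    return _upgma(dm.items, dm.d)


def cluster_from_distance(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage tree straight from a precomputed distance matrix."""
    if len(dm.items) < 2:
        raise ValueError("need at least two items to cluster")
    return _upgma(dm.items, dm.d)


def cut_clusters(tree: Dendrogram, k: int) -> dict[str, int]:
    """Cut the dendrogram into k groups by undoing the k-1 last merges.

    Returns plot -> group label (0..k-1, numbered by first appearance in
    leaf order). k=1 yields one group; k=n yields singletons.
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n + len(tree.merges)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx in range(n - k):  # apply first n-k merges only
        left, right, _, _ = tree.merges[idx]
        node = n + idx
        parent[find(left)] = node
        parent[find(right)] = node

    roots: dict[int, int] = {}
    labels: dict[str, int] = {}
    for leaf_name in tree.leaf_order():
        leaf = tree.leaves.index(leaf_name)
        r = find(leaf)
        if r not in roots:
            roots[r] = len(roots)
        labels[leaf_name] = roots[r]
    return labels


@dataclass
class VennSummary:
    """Taxon sets per group and the cardinality of every Venn region.

    ``regions`` maps a frozenset of group names to the number of taxa
    found in exactly those groups (and no others); empty regions are
    included with count 0. Region counts sum to the size of the union.
    """

    sets: dict[str, set[str]]
    regions: dict[frozenset[str], int]

    def region(self, *groups: str) -> int:
        return self.regions[frozenset(groups)]

    def union_size(self) -> int:
        return len(set().union(*self.sets.values())) if self.sets else 0

    def to_json_dict(self) -> dict[str, int]:
        return {
            "&".join(sorted(k)): v for k, v in sorted(
                self.regions.items(), key=lambda kv: sorted(kv[0])
            )
        }


def venn(
    table: SpecimenTable,
    grouping: Mapping[str, str],
    rank: str = "family",
) -> VennSummary:
    """Taxonomic overlap between plot groups (environments or localities).

    ``grouping`` maps plot id -> group name; at most 5 groups (the
    number of exclusive regions doubles with every added set). Specimens
    with an unknown label at ``rank`` are ignored.
    """
    groups = sorted(set(grouping.values()))
    if len(groups) > 5:
        raise ValueError("venn supports at most 5 groups")
    if not groups:
        raise ValueError("grouping is empty")
    label_col = "otu_label" if rank == "otu" else rank
    df = table.data
    sets: dict[str, set[str]] = {g: set() for g in groups}
    for plot, group in grouping.items():
        sub = df[(df["plot"] == plot) & (df[label_col] != "")]
        sets[group].update(sub[label_col])

    regions: dict[frozenset[str], int] = {}
    universe = set().union(*sets.values())
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            inside = frozenset(combo)
            members = set(universe)
            for g in combo:
                members &= sets[g]
            for g in groups:
                if g not in inside:
                    members -= sets[g]
            regions[inside] = len(members)
    return VennSummary(sets=sets, regions=regions)


def heatmap_table(
    matrix: AbundanceMatrix,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
    *,
    normalize_rows: bool = False,
) -> pd.DataFrame:
    """Reorder an abundance matrix for heatmap display.

    Row/column orders typically come from clustering taxa and plots
    (dendrogram leaf orders); values are untouched unless
    ``normalize_rows`` scales each row to its maximum.
    """
    df = matrix.counts.astype(float)
    if row_order is not None:
        missing = set(row_order) - set(df.index)
        if missing:
            raise KeyError(f"row_order names absent from matrix: {sorted(missing)}")
        df = df.loc[list(row_order)]
    if col_order is not None:
        missing = set(col_order) - set(df.columns)
        if missing:
            raise KeyError(f"col_order names absent from matrix: {sorted(missing)}")
        df = df[list(col_order)]
    if normalize_rows:
        mx = df.max(axis=1).replace(0, np.nan)
        df = df.div(mx, axis=0).fillna(0.0)
    return df
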