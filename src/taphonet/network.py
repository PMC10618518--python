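"""Taphonomic co-occurrence networks over family-level abundances.

Families whose counts rise and fall together across excavation plots
were plausibly deposited from overlapping (micro)habitats, so pairwise
abundance correlation across plots — Pearson, Spearman or Kendall, each
with a two-sided significance test — is turned into an undirected graph:
an edge links two families when their correlation exceeds a floor
(default 0, i.e. positive) at p below a ceiling (default 0.1). Louvain
community detection then segregates the graph into modules, which can be
scored against an independent reference assignment of families to
habitat categories built from functional morphology and the habits of
living relatives (taxonomic uniformitarianism).

Caveats the design reflects: with as few as nine plots, significance is
small-sample (t with n-2 df for Pearson/Spearman; exact Kendall null
where tie-free), and shared zero counts can fabricate correlation — a
``drop_double_zero`` option recomputes each pair only over plots where
at least one member is present.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field


import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .sample_io import AbundanceMatrix

__all__ = [
    "CorrelationMatrix",
    "CoOccurrenceNetwork",
    "ModulePartition",
    "ReferenceAssignment",
    "AgreementReport",
    "pairwise_correlation",
    "build_network",
    "detect_modules",
    "score_agreement",
    "build_bipartite_reference",
    "correlation_semimatrix",
]

METHODS = ("pearson", "spearman", "kendall")


def _corr_and_p(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:  # kendall; exact null when tie-free and n small (scipy's default)
        res = stats.kendalltau(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p


@dataclass
class CorrelationMatrix:
    """All-pairs correlation of taxa across plots.

    ``r`` and ``p`` are symmetric DataFrames (diagonal r=1, p=0);
    ``n_pairs`` holds the number of plots each pair was computed over
    (uniform unless double-zero plots are dropped). Taxa whose counts
    are constant across all plots have no defined correlation; they are
    removed up front and listed in ``excluded_constant``. ``totals``
    carries pooled abundance per taxon for node annotation.
    """

    method: str
    taxa: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n_pairs: pd.DataFrame
    totals: pd.Series
    excluded_constant: list[str] = field(default_factory=list)
    degenerate_pairs: list[tuple[str, str]] = field(default_factory=list)


def pairwise_correlation(
    matrix: AbundanceMatrix,
    method: str = "pearson",
    *,
    drop_double_zero: bool = False,
) -> CorrelationMatrix:
    """Correlate every pair of taxa across plots, with two-sided p-values.

    Requires at least 3 plots. With ``drop_double_zero`` each pair's
    correlation uses only plots where at least one of the two taxa is
    present, countering spurious association from matched absences;
    pairs left with <3 informative plots or a constant sub-vector are
    recorded as degenerate (r=NaN, p=1) and never become edges.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if len(matrix.plots) < 3:
        raise ValueError("need at least 3 plots for correlation")

    counts = matrix.counts.astype(float)
    const = counts.std(axis=1, ddof=0) == 0
    excluded = list(counts.index[const])
    counts = counts.loc[~const]
    taxa = list(counts.index)
    k = len(taxa)
    n_plots = counts.shape[1]

    r = np.eye(k)
    p = np.zeros((k, k))
    n_used = np.full((k, k), n_plots, dtype=int)
    degenerate: list[tuple[str, str]] = []
    X = counts.to_numpy()
    for i, j in itertools.combinations(range(k), 2):
        x, y = X[i], X[j]
        if drop_double_zero:
            keep = (x != 0) | (y != 0)
            x, y = x[keep], y[keep]
        n_used[i, j] = n_used[j, i] = len(x)
        if len(x) < 3 or x.std() == 0 or y.std() == 0:
            r[i, j] = r[j, i] = np.nan
            p[i, j] = p[j, i] = 1.0
            degenerate.append((taxa[i], taxa[j]))
            continue
        rij, pij = _corr_and_p(x, y, method)
        r[i, j] = r[j, i] = rij
        p[i, j] = p[j, i] = pij

    return CorrelationMatrix(
        method=method,
        taxa=taxa,
        r=pd.DataFrame(r, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n_pairs=pd.DataFrame(n_used, index=taxa, columns=taxa),
        totals=matrix.row_totals().loc[taxa],
        excluded_constant=excluded,
        degenerate_pairs=degenerate,
    )


@dataclass
class CoOccurrenceNetwork:
    """Filtered correlation graph: edge iff r > r_min and p < p_max."""

    graph: nx.Graph
    r_min: float
    p_max: float
    isolates: list[str] = field(default_factory=list)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_list(self) -> pd.DataFrame:
        rows = [
            {"u": min(u, v), "v": max(u, v),
             "r": d["r"], "p": d["p"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        return (pd.DataFrame(rows, columns=["u", "v", "r", "p"])
                .sort_values(["u", "v"]).reset_index(drop=True))


def build_network(
    corr: CorrelationMatrix,
    r_min: float = 0.0,
    p_max: float = 0.1,
) -> CoOccurrenceNetwork:
    """Admit edges with correlation strictly above ``r_min`` and p strictly
    below ``p_max``; negative correlations never link under the default.

    Taxa that end up edgeless stay in the graph as flagged isolates.
    """
    g = nx.Graph()
    for t in corr.taxa:
        g.add_node(t, abundance=int(corr.totals[t]))
    rm, pm = corr.r.to_numpy(), corr.p.to_numpy()
    for i, j in itertools.combinations(range(len(corr.taxa)), 2):
        rij, pij = rm[i, j], pm[i, j]
        if np.isnan(rij):
            continue
        if rij > r_min and pij < p_max:
            g.add_edge(corr.taxa[i], corr.taxa[j], r=float(rij), p=float(pij),
                       weight=float(rij))
    return CoOccurrenceNetwork(
        graph=g, r_min=r_min, p_max=p_max,
        isolates=sorted(nx.isolates(g)),
    )


@dataclass
class ModulePartition:
    """Louvain module labels per node plus the achieved modularity."""

    labels: dict[str, int]
    modularity: float
    seed: int
    resolution: float

    @property
    def n_modules(self) -> int:
        return len(set(self.labels.values()))

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.labels.items():
            out.setdefault(m, []).append(node)
        return {m: sorted(v) for m, v in out.items()}


def _louvain_one_level(neigh: dict, degree: dict, m2: float, order: list,
                       resolution: float,
                       rng: np.random.Generator) -> tuple[dict, bool]:
    """Greedy single-node moves until no move improves modularity.

    ``neigh[v]`` maps neighbours to edge weights (self-loops stored once
    under ``neigh[v][v]``); communities are tracked by their total
    degree only, which is all the modularity gain comparison needs.
    Ties in the best gain (including the option of staying put) are
    broken uniformly at random, so restarts can escape plateaus that a
    stay-on-tie rule would freeze.
    """
    com = {v: v for v in order}
    tot = {v: degree[v] for v in order}
    moved_any = False
    improved = True
    sweeps = 0
    while improved and sweeps < 200:  # safety cap against tie oscillation
        improved = False
        sweeps += 1
        for v in order:
            cv = com[v]
            links: dict = {}
            for u, w in neigh[v].items():
                if u != v:
                    links[com[u]] = links.get(com[u], 0.0) + w
            tot[cv] -= degree[v]
            cands = [(cv, links.get(cv, 0.0)
                      - resolution * tot[cv] * degree[v] / m2)]
            for c, w in links.items():
                if c != cv:
                    cands.append((c, w - resolution * tot[c] * degree[v] / m2))
            best_gain = max(gain for _, gain in cands)
            ties = [c for c, gain in cands if gain > best_gain - 1e-12]
            best_c = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
            tot[best_c] = tot.get(best_c, 0.0) + degree[v]
            if best_c != cv:
                com[v] = best_c
                improved = moved_any = True
    return com, moved_any


def _louvain_once(g: nx.Graph, seed: int, resolution: float,
                  wkey: str | None) -> list[set]:
    """One full Louvain pass: local moves + graph aggregation, repeated.

    Node-visit order is shuffled by a generator seeded with ``seed``, so
    a single pass is reproducible and restarts genuinely explore
    different local optima.
    """
    rng = np.random.default_rng(seed)
    nodes = list(g.nodes)
    members = {v: {v} for v in nodes}
    neigh: dict = {v: {} for v in nodes}
    for u, v, d in g.edges(data=True):
        w = float(d[wkey]) if wkey else 1.0
        if u == v:
            neigh[u][u] = neigh[u].get(u, 0.0) + w
        else:
            neigh[u][v] = neigh[u].get(v, 0.0) + w
            neigh[v][u] = neigh[v].get(u, 0.0) + w
    m2 = sum(
        sum(w for u, w in nw.items() if u != v) + 2 * nw.get(v, 0.0)
        for v, nw in neigh.items()
    )
    if m2 == 0:
        return [{v} for v in nodes]
    while len(neigh) > 1:
        order = list(neigh)
        rng.shuffle(order)
        degree = {
            v: sum(w for u, w in neigh[v].items() if u != v)
            + 2 * neigh[v].get(v, 0.0)
            for v in neigh
        }
        com, moved = _louvain_one_level(neigh, degree, m2, order, resolution,
                                        rng)
        if not moved:
            break
        new_members: dict = {}
        for v, c in com.items():
            new_members.setdefault(c, set()).update(members[v])
        new_neigh: dict = {c: {} for c in new_members}
        for v, nw in neigh.items():
            cv = com[v]
            for u, w in nw.items():
                cu = com[u]
                if u == v:
                    new_neigh[cv][cv] = new_neigh[cv].get(cv, 0.0) + w
                elif cu == cv:
                    # internal edge visited from both ends: half each
                    new_neigh[cv][cv] = new_neigh[cv].get(cv, 0.0) + w / 2.0
                else:
                    new_neigh[cv][cu] = new_neigh[cv].get(cu, 0.0) + w
        if len(new_neigh) == len(neigh):
            # tie moves relabelled without coarsening: a fixed point
            members, neigh = new_members, new_neigh
            break
        members, neigh = new_members, new_neigh
    return list(members.values())


def detect_modules(
    net: CoOccurrenceNetwork | nx.Graph,
    seed: int = 0,
    resolution: float = 1.0,
    *,
    weight: str | None = None,
    restarts: int = 10,
) -> ModulePartition:
    """Louvain community detection, best of ``restarts`` seeded runs.

    ``weight``: None treats the graph as unweighted; ``"r"`` weights
    each edge by its correlation coefficient. Isolated nodes come out as
    singleton modules. Reproducible for a fixed (seed, restarts).
    """
    g = net.graph if isinstance(net, CoOccurrenceNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("cannot partition an empty graph")
    wkey = "r" if weight == "r" else None
    best: tuple[float, list[set]] | None = None
    for s in range(seed, seed + max(restarts, 1)):
        comms = _louvain_once(g, s, resolution, wkey)
        q = (nx.community.modularity(g, comms, weight=wkey,
                                     resolution=resolution)
             if g.number_of_edges() else 0.0)
        if best is None or q > best[0]:
            best = (q, comms)
    q, comms = best
    # stable module ids: order communities by their smallest member
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    labels = {node: i for i, comm in enumerate(comms) for node in comm}
    return ModulePartition(labels=labels, modularity=float(q),
                           seed=seed, resolution=resolution)


@dataclass
class ReferenceAssignment:
    """Expert habitat labels per family.

    ``categories`` maps family -> one or more habitat categories (e.g.
    Aquatic / Mudflat / Edaphic / Silvan); ``life_habit`` maps family ->
    "aquatic" or "terrestrial". Families may belong to several habitat
    categories when their life history spans environments.
    """

    categories: dict[str, tuple[str, ...]]
    life_habit: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories = {
            f: tuple(v) if isinstance(v, (tuple, list, set)) else (v,)
            for f, v in self.categories.items()
        }
        bad = {h for h in self.life_habit.values()
               if h not in ("aquatic", "terrestrial")}
        if bad:
            raise ValueError(f"life_habit values must be aquatic/terrestrial, got {bad}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceAssignment":
        """Build from a table with columns family, category[, life_habit].

        A family occurring on several rows accumulates all its categories.
        """
        cats: dict[str, tuple[str, ...]] = {}
        habit: dict[str, str] = {}
        for _, row in df.iterrows():
            fam = str(row["family"]).strip()
            cat = str(row["category"]).strip()
            cur = cats.get(fam, ())
            if cat not in cur:
                cats[fam] = cur + (cat,)
            if "life_habit" in df.columns and pd.notna(row.get("life_habit")):
                habit[fam] = str(row["life_habit"]).strip().lower()
        return cls(categories=cats, life_habit=habit)

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cats in self.categories.values():
            for c in cats:
                sizes[c] = sizes.get(c, 0) + 1
        return sizes


@dataclass
class AgreementReport:
    """How well detected modules match the reference assignment.

    Each module is mapped to the reference category holding the
    plurality of its members (ties broken toward the globally larger
    category, then lexicographically); a node is correct when its own
    reference category set contains its module's mapped category.
    """

    level: str
    fraction_correct: float
    n_scored: int
    module_map: dict[int, str]
    verdicts: pd.DataFrame  # node, module, mapped_category, reference, correct
    unscored: list[str] = field(default_factory=list)


def _node_categories(ref: ReferenceAssignment, level: str,
                     node: str) -> tuple[str, ...]:
    if level == "habitat_category":
        return ref.categories.get(node, ())
    habit = ref.life_habit.get(node)
    return (habit,) if habit else ()


def score_agreement(
    partition: ModulePartition,
    ref: ReferenceAssignment,
    level: str = "habitat_category",
) -> AgreementReport:
    """Fraction of network nodes whose module maps to their reference label.

    Nodes absent from the reference are excluded from the denominator
    and listed in ``unscored``.
    """
    if level not in ("habitat_category", "aquatic_terrestrial"):
        raise ValueError("level must be 'habitat_category' or 'aquatic_terrestrial'")
    scored = {n: _node_categories(ref, level, n)
              for n in partition.labels if _node_categories(ref, level, n)}
    unscored = sorted(set(partition.labels) - set(scored))
    if not scored:
        raise ValueError("no network node appears in the reference assignment")

    if level == "habitat_category":
        global_sizes = ref.category_sizes()
    else:
        global_sizes = {}
        for h in ref.life_habit.values():
            global_sizes[h] = global_sizes.get(h, 0) + 1

    module_map: dict[int, str] = {}
    for mod_id in set(partition.labels.values()):
        votes: dict[str, int] = {}
        for node, m in partition.labels.items():
            if m != mod_id or node not in scored:
                continue
            for cat in scored[node]:
                votes[cat] = votes.get(cat, 0) + 1
        if not votes:
            continue  # module with no referenced member: unmapped
        module_map[mod_id] = min(
            votes,
            key=lambda c: (-votes[c], -global_sizes.get(c, 0), c),
        )

    rows = []
    n_correct = 0
    for node in sorted(scored):
        m = partition.labels[node]
        mapped = module_map.get(m)
        ok = mapped is not None and mapped in scored[node]
        n_correct += ok
        rows.append({
            "node": node, "module": m, "mapped_category": mapped,
            "reference": "|".join(scored[node]), "correct": bool(ok),
        })
    verdicts = pd.DataFrame(rows, columns=["node", "module", "mapped_category",
                                           "reference", "correct"])
    return AgreementReport(
        level=level,
        fraction_correct=n_correct / len(scored),
        n_scored=len(scored),
        module_map=module_map,
        verdicts=verdicts,
        unscored=unscored,
    )


def build_bipartite_reference(ref: ReferenceAssignment) -> nx.Graph:
    """Bipartite family-habitat graph from the reference assignment.

    Family nodes carry ``bipartite=0``, category nodes ``bipartite=1``;
    a family spanning several categories gets one edge per category.
    """
    if not ref.categories:
        raise ValueError("reference assignment is empty")
    g = nx.Graph()
    for fam, cats in ref.categories.items():
        g.add_node(fam, bipartite=0)
        for cat in cats:
            g.add_node(cat, bipartite=1)
            g.add_edge(fam, cat)
    return g


def correlation_semimatrix(corr: CorrelationMatrix) -> pd.DataFrame:
    """Long-format lower triangle with significance stars.

    One row per unordered taxon pair (canonically sorted), with the
    usual banding: *** p<0.01, ** p<0.05, * p<0.1.
    """
    rows = []
    for a, b in itertools.combinations(sorted(corr.taxa), 2):
        r, p = float(corr.r.loc[a, b]), float(corr.p.loc[a, b])
        if p < 0.01:
            sig = "***"
        elif p < 0.05:
            sig = "**"
        elif p < 0.1:
            sig = "*"
        else:
            sig = ""
        rows.append({"u": a, "v": b, "r": r, "p": p, "significance": sig})
    return pd.DataFrame(rows, columns=["u", "v", "r", "p", "significance"])
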