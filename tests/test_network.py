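"""Correlation filtering, co-occurrence graphs, Louvain modules, agreement."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from helpers import brute_force_max_modularity
from taphonet import (
    ReferenceAssignment,
    build_bipartite_reference,
    build_network,
    correlation_semimatrix,
    detect_modules,
    pairwise_correlation,
    score_agreement,
)
from taphonet.network import CoOccurrenceNetwork, CorrelationMatrix, ModulePartition
from taphonet.sample_io import AbundanceMatrix


def _matrix(counts, taxa, plots=None):
    counts = np.asarray(counts, dtype=np.int64)
    plots = plots or [f"P{i + 1}" for i in range(counts.shape[1])]
    return AbundanceMatrix(
        rank="family",
        counts=pd.DataFrame(counts, index=taxa, columns=plots),
    )


def _corr_from(taxa, r_entries, p_entries, totals=None):
    k = len(taxa)
    r = np.eye(k)
    p = np.zeros((k, k))
    for (i, j), val in r_entries.items():
        r[i, j] = r[j, i] = val
    for (i, j), val in p_entries.items():
        p[i, j] = p[j, i] = val
    totals = pd.Series(totals or [1] * k, index=taxa)
    return CorrelationMatrix(
        method="pearson", taxa=list(taxa),
        r=pd.DataFrame(r, index=taxa, columns=taxa),
        p=pd.DataFrame(p, index=taxa, columns=taxa),
        n_pairs=pd.DataFrame(np.full((k, k), 9), index=taxa, columns=taxa),
        totals=totals,
    )


class TestPairwiseCorrelation:
    def test_proportional_rows_give_r_one(self):
        m = _matrix([[1, 2, 3, 4], [2, 4, 6, 8]], ["a", "b"])
        corr = pairwise_correlation(m)
        assert corr.r.loc["a", "b"] == pytest.approx(1.0)

    def test_opposite_pattern_gives_r_minus_one(self):
        m = _matrix([[1, 2, 3], [3, 2, 1]], ["a", "b"])
        corr = pairwise_correlation(m)
        assert corr.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_constant_taxa_flagged_and_excluded(self):
        m = _matrix([[5, 5, 5], [1, 2, 3]], ["const", "var"])
        corr = pairwise_correlation(m)
        assert corr.excluded_constant == ["const"]
        assert corr.taxa == ["var"]

    def test_too_few_plots_rejected(self):
        m = _matrix([[1, 2], [3, 4]], ["a", "b"])
        with pytest.raises(ValueError):
            pairwise_correlation(m)

    @pytest.mark.parametrize("method", ["pearson", "spearman", "kendall"])
    def test_methods_agree_with_scipy(self, method, rng):
        m = _matrix(rng.integers(0, 60, size=(4, 9)), list("abcd"))
        corr = pairwise_correlation(m, method)
        fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr,
              "kendall": stats.kendalltau}[method]
        x = m.counts.loc["a"].to_numpy(float)
        y = m.counts.loc["c"].to_numpy(float)
        ref = fn(x, y)
        assert corr.r.loc["a", "c"] == pytest.approx(float(ref.statistic))
        assert corr.p.loc["a", "c"] == pytest.approx(float(ref.pvalue))

    def test_pearson_significance_threshold_at_nine_plots(self, rng):
        """At n=9, two-sided p<0.1 is exactly |r| > 0.5822 (t inversion, df=7)."""
        t_crit = stats.t.ppf(0.95, 7)
        r_crit = t_crit / np.sqrt(7 + t_crit**2)
        assert r_crit == pytest.approx(0.5822, abs=5e-5)
        for _ in range(200):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            r, p = stats.pearsonr(x, y)
            assert (p < 0.1) == (abs(r) > r_crit)

    def test_double_zero_matching_inflates_correlation(self):
        # two taxa co-present in 2 plots, jointly absent in the rest:
        # the matched zeros manufacture correlation; excluding them
        # must shrink |r| or drop the pair entirely
        m = _matrix([[8, 6, 0, 0, 0, 0, 0, 0, 0],
                     [5, 9, 0, 0, 0, 0, 0, 0, 0]], ["a", "b"])
        full = pairwise_correlation(m)
        dropped = pairwise_correlation(m, drop_double_zero=True)
        r_full = abs(full.r.loc["a", "b"])
        r_drop = dropped.r.loc["a", "b"]
        assert np.isnan(r_drop) or abs(r_drop) < r_full

    def test_drop_double_zero_uses_informative_plots_only(self):
        m = _matrix([[1, 5, 9, 0, 0, 3],
                     [2, 4, 8, 0, 0, 1]], ["a", "b"])
        corr = pairwise_correlation(m, drop_double_zero=True)
        assert corr.n_pairs.loc["a", "b"] == 4


class TestBuildNetwork:
    def test_edge_admission_cases(self):
        corr = _corr_from(
            ["a", "b", "c", "d"],
            {(0, 1): 0.9, (0, 2): 0.9, (0, 3): -0.95},
            {(0, 1): 0.01, (0, 2): 0.2, (0, 3): 0.001,
             (1, 2): 0.9, (1, 3): 0.9, (2, 3): 0.9},
        )
        net = build_network(corr, r_min=0.0, p_max=0.1)
        assert net.graph.has_edge("a", "b")
        assert not net.graph.has_edge("a", "c")  # p too large
        assert not net.graph.has_edge("a", "d")  # negative r never links
        assert "d" in net.isolates and "c" in net.isolates

    def test_strict_inequalities(self):
        corr = _corr_from(["a", "b"], {(0, 1): 0.0}, {(0, 1): 0.05})
        assert build_network(corr, r_min=0.0).n_edges == 0  # r must exceed r_min
        corr2 = _corr_from(["a", "b"], {(0, 1): 0.5}, {(0, 1): 0.1})
        assert build_network(corr2, p_max=0.1).n_edges == 0  # p must be below

    def test_monotone_in_filters(self, rng):
        taxa = list("abcdef")
        r_entries = {(i, j): rng.uniform(-1, 1)
                     for i, j in itertools.combinations(range(6), 2)}
        p_entries = {(i, j): rng.uniform(0, 1)
                     for i, j in itertools.combinations(range(6), 2)}
        corr = _corr_from(taxa, r_entries, p_entries)
        loose = set(map(frozenset, build_network(corr, 0.0, 0.2).graph.edges))
        tight_p = set(map(frozenset, build_network(corr, 0.0, 0.05).graph.edges))
        tight_r = set(map(frozenset, build_network(corr, 0.5, 0.2).graph.edges))
        assert tight_p <= loose and tight_r <= loose

    def test_node_abundance_attribute(self):
        corr = _corr_from(["a", "b"], {(0, 1): 0.9}, {(0, 1): 0.01},
                          totals=[10, 20])
        net = build_network(corr)
        assert net.graph.nodes["b"]["abundance"] == 20


class TestDetectModules:
    def test_two_disconnected_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"),
                          ("x", "y"), ("y", "z"), ("x", "z")])
        net = CoOccurrenceNetwork(graph=g, r_min=0, p_max=0.1)
        part = detect_modules(net, seed=0, restarts=5)
        assert part.n_modules == 2
        assert part.labels["a"] == part.labels["b"] == part.labels["c"]
        assert part.labels["x"] == part.labels["y"] == part.labels["z"]
        best_q, _ = brute_force_max_modularity(g)
        assert part.modularity == pytest.approx(best_q)

    def test_single_node(self):
        g = nx.Graph()
        g.add_node("solo")
        part = detect_modules(CoOccurrenceNetwork(g, 0, 0.1), seed=0)
        assert part.labels == {"solo": 0}

    def test_isolates_become_singletons(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        g.add_node("iso")
        part = detect_modules(CoOccurrenceNetwork(g, 0, 0.1), seed=0)
        assert part.labels["iso"] not in {part.labels["a"]}

    def test_reproducible_for_fixed_seed(self, rng):
        g = nx.gnp_random_graph(20, 0.2, seed=42)
        p1 = detect_modules(CoOccurrenceNetwork(g, 0, 0.1), seed=3, restarts=4)
        p2 = detect_modules(CoOccurrenceNetwork(g, 0, 0.1), seed=3, restarts=4)
        assert p1.labels == p2.labels and p1.modularity == p2.modularity

    def test_matches_exhaustive_maximum_on_small_graphs(self, rng):
        for trial in range(20):
            g = nx.gnp_random_graph(rng.integers(3, 8), 0.45, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            part = detect_modules(CoOccurrenceNetwork(g, 0, 0.1),
                                  seed=0, restarts=20)
            best_q, _ = brute_force_max_modularity(g)
            assert part.modularity == pytest.approx(best_q, abs=1e-9)


REF = ReferenceAssignment(
    categories={"a": ("Aquatic",), "b": ("Aquatic",), "c": ("Aquatic",),
                "m": ("Mudflat",), "n": ("Mudflat",), "s": ("Silvan", "Mudflat")},
    life_habit={"a": "aquatic", "b": "aquatic", "c": "aquatic",
                "m": "terrestrial", "n": "terrestrial", "s": "terrestrial"},
)


class TestScoreAgreement:
    def _partition(self, labels):
        return ModulePartition(labels=labels, modularity=0.5, seed=0,
                               resolution=1.0)

    def test_perfect_partition_scores_one(self):
        part = self._partition({"a": 0, "b": 0, "c": 0, "m": 1, "n": 1})
        rep = score_agreement(part, REF)
        assert rep.fraction_correct == 1.0
        assert rep.module_map == {0: "Aquatic", 1: "Mudflat"}

    def test_plurality_mapping_three_to_one(self):
        part = self._partition({"a": 0, "b": 0, "c": 0, "m": 0})
        rep = score_agreement(part, REF)
        assert rep.module_map[0] == "Aquatic"
        assert rep.fraction_correct == pytest.approx(0.75)

    def test_node_absent_from_reference_excluded(self):
        part = self._partition({"a": 0, "b": 0, "unknown_taxon": 0})
        rep = score_agreement(part, REF)
        assert rep.unscored == ["unknown_taxon"]
        assert rep.n_scored == 2
        assert rep.fraction_correct == 1.0

    def test_multi_category_node_correct_for_either(self):
        part = self._partition({"m": 0, "n": 0, "s": 0})
        rep = score_agreement(part, REF)
        assert rep.module_map[0] == "Mudflat"
        assert bool(rep.verdicts.set_index("node").loc["s", "correct"])

    def test_tie_breaks_toward_globally_larger_category(self):
        # one aquatic + one mudflat member: global Aquatic (3) > Mudflat (3)?
        # categories: Aquatic appears 3x, Mudflat 3x (m, n, s) -> then lexicographic
        part = self._partition({"a": 0, "m": 0})
        rep = score_agreement(part, REF)
        assert rep.module_map[0] == "Aquatic"  # sizes tie at 3; "Aquatic" < "Mudflat"

    def test_refinement_of_pure_modules_scores_one(self):
        part = self._partition({"a": 0, "b": 1, "c": 1, "m": 2, "n": 3})
        assert score_agreement(part, REF).fraction_correct == 1.0

    def test_life_habit_level(self):
        part = self._partition({"a": 0, "b": 0, "m": 0, "n": 1, "s": 1})
        rep = score_agreement(part, REF, "aquatic_terrestrial")
        assert rep.fraction_correct == pytest.approx(4 / 5)

    def test_empty_overlap_raises(self):
        part = self._partition({"nope": 0})
        with pytest.raises(ValueError):
            score_agreement(part, REF)


class TestBipartiteReference:
    def test_multi_membership_edge_count(self):
        ref = ReferenceAssignment(categories={
            "f1": ("Aquatic",), "f2": ("Mudflat",), "f3": ("Aquatic", "Mudflat")})
        g = build_bipartite_reference(ref)
        assert g.number_of_edges() == 4

    def test_category_degree_equals_family_count(self):
        g = build_bipartite_reference(REF)
        assert g.degree("Aquatic") == 3
        assert g.degree("Mudflat") == 3  # m, n, s

    def test_projection_yields_clique_per_category(self):
        ref = ReferenceAssignment(categories={
            "f1": ("A",), "f2": ("A",), "f3": ("A",), "g1": ("B",), "g2": ("B",)})
        g = build_bipartite_reference(ref)
        proj = nx.bipartite.projected_graph(
            g, [n for n, d in g.nodes(data=True) if d["bipartite"] == 0])
        expected = set(map(frozenset, [("f1", "f2"), ("f1", "f3"),
                                       ("f2", "f3"), ("g1", "g2")]))
        assert set(map(frozenset, proj.edges)) == expected


class TestSemimatrix:
    def test_row_count_and_banding(self):
        taxa = list("abcd")
        p_entries = {(0, 1): 0.005, (0, 2): 0.04, (0, 3): 0.09,
                     (1, 2): 0.5, (1, 3): 0.2, (2, 3): 0.099}
        corr = _corr_from(taxa, {k: 0.5 for k in p_entries}, p_entries)
        sm = correlation_semimatrix(corr)
        assert len(sm) == 6  # k(k-1)/2
        stars = dict(zip(zip(sm["u"], sm["v"]), sm["significance"]))
        assert stars[("a", "b")] == "***"
        assert stars[("a", "c")] == "**"
        assert stars[("a", "d")] == "*"
        assert stars[("b", "c")] == ""

    def test_canonical_order_invariant_to_taxa_permutation(self):
        p_entries = {(0, 1): 0.01, (0, 2): 0.5, (1, 2): 0.07}
        r_entries = {(0, 1): 0.9, (0, 2): 0.1, (1, 2): 0.6}
        a = correlation_semimatrix(_corr_from(["x", "y", "z"], r_entries, p_entries))
        # same data with taxa listed in a different order
        perm = [2, 0, 1]  # z, x, y
        r2 = {(perm.index(i), perm.index(j)) if perm.index(i) < perm.index(j)
              else (perm.index(j), perm.index(i)): v
              for (i, j), v in r_entries.items()}
        p2 = {(perm.index(i), perm.index(j)) if perm.index(i) < perm.index(j)
              else (perm.index(j), perm.index(i)): v
              for (i, j), v in p_entries.items()}
        b = correlation_semimatrix(_corr_from(["z", "x", "y"], r2, p2))
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True))
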