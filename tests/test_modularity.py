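"""Modularity measures, greedy detection and module quality."""

import networkx as nx
import numpy as np
import pytest

from modulin.modularity import (
    Partition,
    WeightScheme,
    adjusted_rand_index,
    compare_quality,
    filter_small_modules,
    greedy_modules,
    m_dli_ddi,
    m_dli_ddi_terms,
    m_ppi,
    module_quality,
    newman_modularity,
)
from modulin.network import AnnotatedNetwork, AnnotationTable, InteractionRecord
from modulin.synthetic import PlantedModel, generate_planted_network

from conftest import build_network, clique_edges
from oracles import best_partition_exhaustive, direct_modularity


def as_annotated(graph: nx.Graph, labels=None) -> AnnotatedNetwork:
    net = AnnotatedNetwork()
    for u, v in graph.edges():
        label = labels.get((u, v), "unclassified") if labels else "unclassified"
        net.add_edge(InteractionRecord(a=f"n{u}", b=f"n{v}", label=label))
    return net


class TestMPPI:
    def test_single_module_partition_is_zero(self, two_cliques):
        part = Partition(assignment={n: 0 for n in two_cliques.graph.nodes()})
        assert m_ppi(two_cliques, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles_give_half(self):
        net = build_network(clique_edges(["X0", "X1", "X2"]) +
                            clique_edges(["Y0", "Y1", "Y2"]))
        part = Partition(assignment={f"{g}{i}": k
                                     for k, g in enumerate("XY") for i in range(3)})
        assert m_ppi(net, part) == pytest.approx(0.5)

    def test_matches_direct_summation_oracle_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            graph = nx.gnp_random_graph(15, 0.3, seed=int(rng.integers(2**31)))
            if graph.number_of_edges() == 0:
                continue
            net = as_annotated(graph)
            assignment = {f"n{u}": int(rng.integers(4)) for u in graph.nodes()}
            part = Partition(assignment=assignment)
            groups = {}
            for u in graph.nodes():
                groups.setdefault(assignment[f"n{u}"], set()).add(u)
            oracle = direct_modularity(graph, groups.values())
            assert m_ppi(net, part) == pytest.approx(oracle, abs=1e-12)

    def test_bounds_and_singleton_partition(self):
        model = PlantedModel(module_sizes=(10, 10), p_in=0.5, p_out=0.1, seed=1)
        u = generate_planted_network(model)
        q = m_ppi(u.network, u.truth_partition)
        assert -1.0 <= q <= 1.0
        singletons = Partition(assignment={
            n: i for i, n in enumerate(sorted(u.network.graph.nodes()))})
        assert m_ppi(u.network, singletons) <= 0.0


class TestMDliDdi:
    def test_without_dlis_reduces_to_ddi_only_newman(self):
        net = build_network(clique_edges(["a", "b", "c"], label="DDI") +
                            clique_edges(["x", "y", "z"], label="DDI"))
        part = Partition.from_groups([{"a", "b", "c"}, {"x", "y", "z"}])
        with pytest.warns(UserWarning, match="no DLI"):
            value = m_dli_ddi(net, part)
        assert value == pytest.approx(m_ppi(net, part))

    def test_prefers_ddis_within_and_dlis_on_boundaries(self):
        within = (clique_edges(["a", "b", "c"], label="DDI")
                  + clique_edges(["x", "y", "z"], label="DDI"))
        net_good = build_network(within + [("a", "x", "DLI"), ("b", "y", "DLI")])
        part = Partition.from_groups([{"a", "b", "c"}, {"x", "y", "z"}])
        good = m_dli_ddi(net_good, part)
        # swap every label: DDIs now bridge, DLIs now sit within modules
        net_bad = net_good.copy()
        for rec in net_good.edges():
            net_bad.set_label(rec.a, rec.b, "DLI" if rec.label == "DDI" else "DDI")
        assert good > m_dli_ddi(net_bad, part)

    def test_boundary_dli_counted_once_per_incident_module(self):
        net = build_network(clique_edges(["a", "b", "c"], label="DDI")
                            + clique_edges(["x", "y", "z"], label="DDI")
                            + [("a", "x", "DLI")])
        part = Partition.from_groups([{"a", "b", "c"}, {"x", "y", "z"}])
        terms = m_dli_ddi_terms(net, part)
        assert sum(row["l_BL"] for row in terms.per_module.values()) == 2

    def test_chance_terms_match_label_respecting_rewiring_oracle(self):
        # the expected boundary fraction 2q(1-q) should match degree-preserving
        # rewirings of the DLI edges (configuration model via double-edge swaps)
        rng = np.random.default_rng(8)
        model = PlantedModel(module_sizes=(12, 12, 12), p_in=0.5, p_out=0.1,
                             beta_within_ddi=0.7, beta_between_dli=0.7, seed=31)
        u = generate_planted_network(model)
        part = u.truth_partition
        terms = m_dli_ddi_terms(u.network, part)
        dli_graph = nx.Graph(
            (r.a, r.b) for r in u.network.edges() if r.label == "DLI")
        assign = part.assignment
        mods = sorted({assign[n] for n in u.network.graph.nodes()})
        samples = []
        for _ in range(400):
            g = dli_graph.copy()
            nx.double_edge_swap(g, nswap=4 * g.number_of_edges(),
                                max_tries=10**5, seed=int(rng.integers(2**31)))
            boundary = {m: 0 for m in mods}
            for a, b in g.edges():
                if assign[a] != assign[b]:
                    boundary[assign[a]] += 1
                    boundary[assign[b]] += 1
            samples.append([boundary[m] / g.number_of_edges() for m in mods])
        samples = np.array(samples)
        expected = np.array([
            2 * q * (1 - q)
            for q in (
                np.array([terms.per_module[m]["d_L"] for m in mods]) / (2 * terms.l_l)
            )
        ])
        # the closed form assumes stub matching with replacement; rewirings
        # preserve simplicity, so compare against the null spread (3 sd)
        sd = samples.std(axis=0)
        assert np.all(np.abs(samples.mean(axis=0) - expected) < 3 * sd)


class TestGreedyModules:
    def test_two_cliques_match_exhaustive_search(self, two_cliques):
        res = greedy_modules(two_cliques)
        graph = two_cliques.graph
        best_q, best = best_partition_exhaustive(graph)
        found = sorted(frozenset(s) for s in res.partition.modules().values())
        assert found == sorted(frozenset(s) for s in best)
        assert res.modularity == pytest.approx(best_q, abs=1e-12)

    def test_triangle_ring_recovers_triangles(self, triangle_ring):
        res = greedy_modules(triangle_ring)
        modules = sorted(frozenset(s) for s in res.partition.modules().values())
        expected = sorted(
            frozenset({f"T{t}a", f"T{t}b", f"T{t}c"}) for t in range(4))
        assert modules == expected
        # no coarsening of the triangle partition scores higher
        from oracles import set_partitions

        graph = triangle_ring.graph
        blocks = [set(b) for b in expected]
        for merged in set_partitions(range(4)):
            groups = [set().union(*(blocks[i] for i in part)) for part in merged]
            assert direct_modularity(graph, groups) <= res.modularity + 1e-12

    def test_agrees_with_igraph_fastgreedy(self, two_cliques, triangle_ring):
        igraph = pytest.importorskip("igraph")
        for net in (two_cliques, triangle_ring):
            nodes = sorted(net.graph.nodes())
            index = {n: i for i, n in enumerate(nodes)}
            g = igraph.Graph(
                n=len(nodes),
                edges=[(index[a], index[b]) for a, b in net.graph.edges()],
            )
            dendro = g.community_fastgreedy()
            clusters = dendro.as_clustering()
            mine = greedy_modules(net)
            theirs = {nodes[v]: c for c, members in enumerate(clusters)
                      for v in members}
            assert adjusted_rand_index(mine.partition.assignment, theirs) == 1.0

    def test_deterministic_and_traced(self, two_cliques):
        r1 = greedy_modules(two_cliques)
        r2 = greedy_modules(two_cliques)
        assert r1.partition.assignment == r2.partition.assignment
        assert [(e.module_a, e.module_b) for e in r1.trace] == [
            (e.module_a, e.module_b) for e in r2.trace]
        assert [e.step for e in r1.trace] == list(range(1, len(r1.trace) + 1))

    def test_empty_network_is_an_error(self):
        with pytest.raises(ValueError):
            greedy_modules(AnnotatedNetwork())

    def test_components_never_merge(self):
        net = build_network(clique_edges(["a", "b", "c"]) +
                            clique_edges(["x", "y", "z"]))
        res = greedy_modules(net)
        assignment = res.partition.assignment
        assert assignment["a"] != assignment["x"]


class TestWeightedFixture:
    """Channel clique {H1..H4} (one internal DDI) with DLI bridges from H2 to
    the signalling group {F1,F2,F3}: interface weights keep the groups apart
    while plain topology pulls the bridged protein into the other group."""

    def _fixture(self):
        H = ["H1", "H2", "H3", "H4"]
        edges = []
        from itertools import combinations

        for a, b in combinations(H, 2):
            edges.append((a, b, "DDI" if {a, b} == {"H2", "H4"} else "unclassified"))
        edges += [("F1", "F2"), ("F2", "F3"), ("F1", "F3")]
        edges += [("H2", "F1", "DLI"), ("H2", "F2", "DLI"), ("H2", "F3", "DLI")]
        return build_network(edges)

    def test_unweighted_merges_bridged_protein_into_other_group(self):
        net = self._fixture()
        res = greedy_modules(net)
        a = res.partition.assignment
        assert any(a["H2"] == a[f] for f in ("F1", "F2", "F3"))

    def test_weighted_keeps_groups_separate(self):
        net = self._fixture()
        res = greedy_modules(net, weights=WeightScheme(w_ddi=100, w_dli=0.1))
        a = res.partition.assignment
        for h in ("H1", "H2", "H3", "H4"):
            for f in ("F1", "F2", "F3"):
                assert a[h] != a[f]
        # the DDI pair merges first in the weighted trace
        assert res.merge_step_of("H2", "H4") == 1


class TestSmallModuleFilter:
    def test_flagging_rules(self):
        part = Partition(assignment={"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 2})
        flagged = filter_small_modules(part)
        assert flagged.excluded == {1, 2}
        assert flagged.assignment == part.assignment

    def test_nothing_flagged_when_all_large(self):
        part = Partition.from_groups([{"a", "b", "c"}, {"x", "y", "z"}])
        assert filter_small_modules(part).excluded == set()


class TestModuleQuality:
    def test_jaccard_values(self):
        from modulin.modularity import annotation_jaccard

        assert annotation_jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert annotation_jaccard({"a", "b"}, {"b", "c"}) == pytest.approx(1 / 3)

    def test_random_partition_has_unit_fold_increase(self):
        rng = np.random.default_rng(6)
        folds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            proteins = [f"p{i}" for i in range(60)]
            ann = AnnotationTable.from_groups({
                f"T{t}": {p for p in proteins if rng.random() < 0.3}
                for t in range(6)
            })
            part = Partition(assignment={p: int(rng.integers(5)) for p in proteins})
            try:
                folds.append(module_quality(part, ann).fold_increase)
            except ValueError:
                continue
        folds = np.array(folds)
        se = folds.std(ddof=1) / np.sqrt(len(folds))
        assert abs(folds.mean() - 1.0) < 3 * se + 0.05

    def test_compare_quality_effect_size(self):
        rng = np.random.default_rng(12)
        a = np.clip(rng.normal(0.6, 0.1, size=100), 0, 1)
        b = np.clip(rng.normal(0.4, 0.1, size=100), 0, 1)
        from modulin.modularity import QualityReport

        ra = QualityReport({i: float(v) for i, v in enumerate(a)}, a.mean(), 1, 1, 0)
        rb = QualityReport({i: float(v) for i, v in enumerate(b)}, b.mean(), 1, 1, 0)
        comp = compare_quality(ra, rb)
        assert comp.cohen_d == pytest.approx(2.0, abs=0.4)
        assert comp.ks_p < 1e-10
        same = compare_quality(ra, ra)
        assert same.cohen_d == 0.0


class TestDissociation:
    def test_adding_boundary_dlis_lowers_mppi_but_not_mdliddi(self):
        """The Fig-5-style dissociation: progressively adding between-module
        DLI edges strictly decreases topological modularity while the
        interface-aware measure does not decrease."""
        rng = np.random.default_rng(9)
        # start from modules whose few DLIs all sit inside modules, so the
        # boundary fraction of DLIs starts at zero and rises with each batch
        model = PlantedModel(module_sizes=(15, 15, 15), p_in=0.5, p_out=0.0,
                             beta_within_ddi=0.85, seed=77)
        u = generate_planted_network(model)
        net = u.network
        part = u.truth_partition
        nodes = sorted(net.graph.nodes())
        assign = part.assignment
        mppi_values, rev_values = [], []
        candidates = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1:]
                      if assign[a] != assign[b] and not net.graph.has_edge(a, b)]
        rng.shuffle(candidates)
        current = net.copy()
        for batch in range(5):
            mppi_values.append(m_ppi(current, part))
            rev_values.append(m_dli_ddi(current, part))
            current = current.copy()
            for _ in range(15):
                a, b = candidates.pop()
                current.add_edge(InteractionRecord(a=a, b=b, label="DLI"))
        for earlier, later in zip(mppi_values, mppi_values[1:]):
            assert later < earlier
        for earlier, later in zip(rev_values, rev_values[1:]):
            assert later >= earlier - 1e-12


class TestAdjustedRand:
    def test_identical_partitions_score_one(self):
        labels = {f"p{i}": i % 3 for i in range(30)}
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_matches_sklearn(self):
        sklearn = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(1)
        keys = [f"p{i}" for i in range(50)]
        for _ in range(10):
            a = {k: int(rng.integers(4)) for k in keys}
            b = {k: int(rng.integers(4)) for k in keys}
            expected = sklearn.adjusted_rand_score(
                [a[k] for k in keys], [b[k] for k in keys])
            assert adjusted_rand_index(a, b) == pytest.approx(expected)
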