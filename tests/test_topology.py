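from math import comb

import networkx as nx
import numpy as np
import pytest

from cernet.topology import (
    classify_hubs,
    fit_power_law,
    hub_subnetwork,
    identify_hubs,
    kcore,
    mutation_overlay,
    powerlaw_check,
    union_subnetwork,
)
from cernet.cerna import CeRNANetwork
from cernet.dysreg import DysregNetwork


def naive_peeling(graph: nx.Graph) -> dict:
    """Repeated-scan peeling oracle for core indices."""
    core = {}
    g = nx.Graph(graph)
    k = 0
    while g.number_of_nodes():
        k += 1
        while True:
            doomed = [n for n, d in g.degree() if d < k]
            if not doomed:
                break
            for n in doomed:
                core[n] = k - 1
                g.remove_node(n)
    return core


class TestIdentifyHubs:
    def test_distinct_degrees(self):
        g = nx.Graph()
        # 20 nodes with distinct degrees via a threshold-like construction
        g.add_nodes_from(range(20))
        for i in range(20):
            for j in range(i + 1, 20):
                if i + j >= 19:
                    g.add_edge(i, j)
        degrees = dict(g.degree())
        assert len(set(degrees.values())) >= 19
        hubs = identify_hubs(g)
        top2 = sorted(degrees, key=degrees.get, reverse=True)[:2]
        assert hubs == set(top2)

    def test_all_tied(self):
        g = nx.circulant_graph(10, [1, 2])  # 10 nodes, all degree 4
        assert identify_hubs(g) == set(g.nodes)

    def test_star_pathology_boundary_tie(self):
        # star on 11 nodes: c = ceil(1.1) = 2, the 2nd highest degree is a
        # leaf (degree 1), so the inclusive tie rule pulls in every leaf
        g = nx.star_graph(10)
        assert identify_hubs(g) == set(g.nodes)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            identify_hubs(nx.Graph())

    def test_relabel_invariance(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        mapping = {n: f"node_{(n * 17) % 40}" for n in g.nodes}
        hubs = identify_hubs(g)
        hubs_relabeled = identify_hubs(nx.relabel_nodes(g, mapping))
        assert hubs_relabeled == {mapping[n] for n in hubs}


class TestClassifyHubs:
    HUBS = {
        "s1": {"A", "B", "C", "E"},
        "s2": {"A", "B", "E"},
        "s3": {"A", "B"},
        "s4": {"A", "D"},
    }

    def test_partition(self):
        cat = classify_hubs(self.HUBS)
        assert cat.classification["A"] == "common"  # 4 networks
        assert cat.classification["B"] == "common"  # 3 networks
        assert cat.classification["C"] == "specific"  # exactly 1
        assert cat.classification["D"] == "specific"
        assert cat.classification["E"] == "intermediate"  # exactly 2
        union = set().union(*self.HUBS.values())
        assert cat.common | cat.specific | cat.intermediate == union
        assert len(cat.common) + len(cat.specific) + len(cat.intermediate) == len(union)

    def test_common_fraction(self):
        cat = classify_hubs(self.HUBS)
        assert cat.common_fraction("s3") == pytest.approx(1.0)
        assert cat.common_fraction("s1") == pytest.approx(2 / 4)

    def test_strict_specific_variant(self):
        nodes = {
            "s1": {"A", "B", "C", "E", "X"},  # C present (non-hub) in s2 too
            "s2": {"A", "B", "C", "E"},
            "s3": {"A", "B"},
            "s4": {"A", "D"},
        }
        cat = classify_hubs(self.HUBS, strict_specific=True, node_sets=nodes)
        assert cat.classification["C"] == "intermediate", "present elsewhere as non-hub"
        assert cat.classification["D"] == "specific"

    def test_needs_three_networks(self):
        with pytest.raises(ValueError):
            classify_hubs({"s1": {"A"}, "s2": {"B"}})


class TestKCore:
    def test_triangle_with_pendant(self):
        g = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3)])
        res = kcore(g)
        assert res.core == {0: 2, 1: 2, 2: 2, 3: 1}
        assert res.normalized[0] == 1.0 and res.normalized[3] == 0.5

    def test_complete_graph(self):
        res = kcore(nx.complete_graph(5))
        assert all(k == 4 for k in res.core.values())
        assert all(v == 1.0 for v in res.normalized.values())

    def test_path(self):
        res = kcore(nx.path_graph(4))
        assert set(res.core.values()) == {1}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            kcore(nx.Graph())

    def test_matches_naive_peeling_oracle(self):
        rng = np.random.default_rng(9)
        for i in range(30):
            n = int(rng.integers(5, 51))
            p = float(rng.uniform(0.03, 0.4))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 30)))
            assert kcore(g).core == naive_peeling(g)

    def test_edge_removal_never_raises_core(self):
        g = nx.gnp_random_graph(30, 0.2, seed=4)
        base = kcore(g).core
        rng = np.random.default_rng(5)
        edges = list(g.edges)
        for idx in rng.choice(len(edges), size=5, replace=False):
            h = nx.Graph(g)
            h.remove_edge(*edges[idx])
            pruned = kcore(h).core
            assert all(pruned[n] <= base[n] for n in h.nodes)


class TestPowerLaw:
    def test_exact_table(self):
        exponent, r2 = fit_power_law({1: 16, 2: 4, 4: 1})  # f(d) = 16 d^-2
        assert exponent == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)

    def test_regular_graph_errors(self):
        with pytest.raises(ValueError, match="single distinct degree"):
            powerlaw_check(nx.cycle_graph(10))

    def test_scale_free_fits_better_than_random(self):
        ba = nx.barabasi_albert_graph(2000, 5, seed=0)
        er = nx.gnp_random_graph(2000, 0.005, seed=0)
        _, r2_ba = powerlaw_check(ba)
        _, r2_er = powerlaw_check(er)
        assert r2_ba > r2_er + 0.1


class TestHubSubnetwork:
    def _cerna(self, subtype, edges):
        net = CeRNANetwork(subtype)
        for a, b in edges:
            net.graph.add_node(a, rna_class="mRNA")
            net.graph.add_node(b, rna_class="mRNA")
            net.graph.add_edge(a, b, weight=1, n_shared=2, shared_fdr=1e-4, r=0.8, corr_fdr=1e-4)
        return net

    def _dysreg(self, edges):
        net = DysregNetwork("s1")
        for m, t in edges:
            net.graph.add_node(m, kind="miRNA")
            net.graph.add_node(t, kind="target", rna_class="mRNA")
            net.graph.add_edge(m, t, r=-0.5, p=1e-3)
        return net

    def test_isolated_hubs_keep_nodes(self):
        net = self._cerna("s1", [("A", "B"), ("C", "D")])
        dys = self._dysreg([("m1", "A")])
        sub, _ = hub_subnetwork(net, {"A", "C"}, dys)
        assert set(sub.nodes) == {"A", "C"} and sub.number_of_edges() == 0

    def test_multiplicity_annotation(self):
        nets = {s: self._cerna(s, [("A", "B")]) for s in ["s1", "s2", "s3"]}
        nets["s4"] = self._cerna("s4", [("A", "C")])
        union = union_subnetwork(nets, {"A", "B", "C"})
        assert union.edges["A", "B"]["multiplicity"] == 3
        assert union.edges["A", "C"]["multiplicity"] == 1

    def test_mirna_annotation_flag(self):
        net = self._cerna("s1", [("A", "B")])
        # m1 regulates 3 targets (hub miRNA), m2 regulates only A
        dys = self._dysreg([("m1", "A"), ("m1", "B"), ("m1", "X"), ("m2", "A")])
        _, only_hubs = hub_subnetwork(net, {"A", "B"}, dys, hub_mirnas_only=True)
        assert only_hubs == [("m1", "A"), ("m1", "B")]
        _, all_regs = hub_subnetwork(net, {"A", "B"}, dys, hub_mirnas_only=False)
        assert ("m2", "A") in all_regs

    def test_unknown_hub_errors(self):
        net = self._cerna("s1", [("A", "B")])
        with pytest.raises(ValueError, match="absent"):
            hub_subnetwork(net, {"Z"}, self._dysreg([]))


class TestMutationOverlay:
    def test_mutated_equals_hubs_gives_minimal_p(self):
        g = nx.barbell_graph(5, 2)  # 12 nodes
        hubs = identify_hubs(g)
        cores = kcore(g)
        res = mutation_overlay(g, hubs, hubs, cores)
        assert res.hub_enrichment_p == pytest.approx(1 / comb(len(g), len(hubs)))

    def test_complete_separation_hits_enumeration_minimum(self):
        # kernel-level check: with tie-free values and every mutated degree
        # strictly larger, the one-sided exact p is the smallest attainable
        from cernet._stats import rank_sum_test

        rng = np.random.default_rng(3)
        for n1, n2 in [(2, 5), (3, 4), (1, 6)]:
            lo = np.sort(rng.uniform(0, 1, n2))
            hi = np.sort(rng.uniform(2, 3, n1))
            res = rank_sum_test(hi, lo, alternative="greater")
            assert res.method == "exact"
            assert res.pvalue == pytest.approx(1 / comb(n1 + n2, n1))

    def test_degree_comparison_consistent_with_kernel(self):
        from cernet._stats import rank_sum_test

        g = nx.star_graph(6)
        cores = kcore(g)
        res = mutation_overlay(g, {0}, {0}, cores)
        degrees = dict(g.degree())
        expected = rank_sum_test(
            np.array([degrees[0]], dtype=float),
            np.array([degrees[n] for n in sorted(set(g) - {0})], dtype=float),
            alternative="greater",
        )
        assert res.degree_p == pytest.approx(expected.pvalue)
        assert res.mean_layer_mutated >= res.mean_layer_other

    def test_random_mutated_sets_calibrated(self):
        g = nx.gnp_random_graph(40, 0.15, seed=6)
        hubs = identify_hubs(g)
        cores = kcore(g)
        rng = np.random.default_rng(7)
        nodes = list(g.nodes)
        pvals = []
        for _ in range(200):
            mutated = rng.choice(nodes, size=8, replace=False)
            pvals.append(mutation_overlay(g, set(mutated), hubs, cores).hub_enrichment_p)
        assert np.mean(np.array(pvals) <= 0.05) <= 0.10, "type-I rate near or below nominal"

    def test_no_mutated_in_network_warns(self):
        g = nx.path_graph(4)
        with pytest.warns(UserWarning, match="overlay undefined"):
            assert mutation_overlay(g, {"absent"}, {0}, kcore(g)) is None
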