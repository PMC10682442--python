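"""Common/specific algebra, Markov clustering, lncRNA/circRNA module filter."""

import itertools

import numpy as np
import pytest

from cernapipe.datatypes import RNAClass
from cernapipe.netops import (common_network, filter_lc_modules, mcl_cluster,
                              specific_network)
from cernapipe.simulate import generate
from conftest import make_network, small_generator_config
from oracles import reference_mcl_partition


def random_network_family(rng, n_networks=5, n_nodes=14, p_edge=0.25, tag="fam"):
    classes = {f"g{i}": (RNAClass.MRNA, RNAClass.LNCRNA, RNAClass.CIRCRNA)[i % 3]
               for i in range(n_nodes)}
    nets = {}
    for k in range(n_networks):
        edges = [(a, b) for a, b in itertools.combinations(classes, 2)
                 if rng.random() < p_edge]
        weights = [float(rng.uniform(0.4, 1.0)) for _ in edges]
        nets[f"{tag}{k}"] = make_network(edges, classes, tag=f"{tag}{k}",
                                         weights=weights)
    return nets


CL = {"a": RNAClass.MRNA, "b": RNAClass.LNCRNA, "c": RNAClass.CIRCRNA,
      "d": RNAClass.MRNA}


class TestAlgebra:
    def test_identical_networks_idempotent(self):
        net = make_network([("a", "b"), ("b", "c")], CL)
        common = common_network({"x": net, "y": net})
        assert common.edge_set() == net.edge_set()
        assert common.node_set() == net.node_set()
        spec = specific_network(net, common)
        assert spec.n_edges == 0 and spec.n_nodes == 0

    def test_disjoint_networks_empty_common(self):
        n1 = make_network([("a", "b")], {"a": CL["a"], "b": CL["b"]})
        n2 = make_network([("c", "d")], {"c": CL["c"], "d": CL["d"]})
        common = common_network({"x": n1, "y": n2})
        assert common.n_nodes == 0 and common.n_edges == 0
        assert specific_network(n1, common).edge_set() == n1.edge_set()

    def test_set_algebra_on_random_networks(self, rng):
        """common subset of each primary; specific disjoint from common;
        |E_specific| = |E^C| - |E^C ∩ E^common| -- all checked against
        plain Python set arithmetic."""
        for rep in range(20):
            fam = random_network_family(rng)
            common = common_network(fam)
            edge_sets = {k: n.edge_set() for k, n in fam.items()}
            expected_common = set.intersection(*edge_sets.values())
            assert common.edge_set() == expected_common
            assert common.node_set() == set.intersection(
                *(n.node_set() for n in fam.values()))
            for k, net in fam.items():
                spec = specific_network(net, common)
                assert spec.edge_set() == edge_sets[k] - expected_common
                assert spec.edge_set() & common.edge_set() == set()
                assert len(spec.edge_set()) == \
                    len(edge_sets[k]) - len(edge_sets[k] & expected_common)
                assert spec.node_set() == {n for e in spec.edge_set() for n in e}

    def test_common_weight_is_mean(self):
        n1 = make_network([("a", "b")], CL, weights=[0.5])
        n2 = make_network([("a", "b")], CL, weights=[0.9])
        common = common_network({"x": n1, "y": n2})
        assert common.graph.edges["a", "b"]["weight"] == pytest.approx(0.7)

    def test_node_difference_count_reported(self):
        n1 = make_network([("a", "b"), ("c", "d")], CL)
        n2 = make_network([("a", "b")], {"a": CL["a"], "b": CL["b"]})
        common = common_network({"x": n1, "y": n2})
        spec = specific_network(n1, common)
        assert spec.graph.graph["node_difference_count"] == \
            len(n1.node_set() - common.node_set())

    def test_ground_truth_common_recovery(self):
        cohort = generate(small_generator_config(
            seed=9, n_outliers=0, subtypes=tuple(zip("ABCDE", (100,) * 5))))
        from cernapipe.cerna import build_primary_network
        prim = {lbl: build_primary_network(ds, cohort.interactions)
                for lbl, ds in cohort.expression.items()}
        common = common_network(prim)
        assert cohort.truth.common_edges() <= common.edge_set()
        for lbl in prim:
            spec = specific_network(prim[lbl], common)
            assert cohort.truth.specific_edges(lbl) & common.edge_set() == set()
            # own specific edges present for this seed
            assert cohort.truth.specific_edges(lbl) <= spec.edge_set()


def clique_edges(nodes):
    return list(itertools.combinations(nodes, 2))


class TestMCL:
    def test_two_disjoint_triangles(self):
        classes = {f"g{i}": RNAClass.MRNA for i in range(6)}
        net = make_network(clique_edges(["g0", "g1", "g2"])
                           + clique_edges(["g3", "g4", "g5"]), classes)
        ms = mcl_cluster(net)
        assert sorted(ms.modules) == [("g0", "g1", "g2"), ("g3", "g4", "g5")]

    def test_single_node(self):
        net = make_network([], {"solo": RNAClass.LNCRNA})
        ms = mcl_cluster(net)
        assert ms.modules == [("solo",)]

    def test_weak_bridge_between_cliques(self):
        classes = {f"g{i}": RNAClass.MRNA for i in range(12)}
        left, right = [f"g{i}" for i in range(6)], [f"g{i}" for i in range(6, 12)]
        edges = clique_edges(left) + clique_edges(right) + [("g5", "g6")]
        weights = [0.8] * 30 + [0.01]
        ms = mcl_cluster(make_network(edges, classes, weights=weights))
        assert sorted(ms.modules) == [tuple(sorted(left)), tuple(sorted(right))]

    def test_matches_reference_implementation(self, rng):
        for rep in range(20):
            n = int(rng.integers(6, 16))
            a = np.zeros((n, n))
            # modular random graph: two blocks + sparse cross edges
            for i in range(n):
                for j in range(i + 1, n):
                    same = (i < n // 2) == (j < n // 2)
                    if rng.random() < (0.7 if same else 0.08):
                        a[i, j] = a[j, i] = rng.uniform(0.4, 1.0)
            classes = {f"n{i:02d}": RNAClass.MRNA for i in range(n)}
            names = sorted(classes)
            edges, weights = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    if a[i, j] > 0:
                        edges.append((names[i], names[j]))
                        weights.append(a[i, j])
            net = make_network(edges, classes, weights=weights)
            ours = {frozenset(m) for m in mcl_cluster(net).modules}
            ref = reference_mcl_partition(a)
            ref_named = {frozenset(names[i] for i in grp) for grp in ref}
            assert ours == ref_named

    def test_node_order_permutation_invariance(self, rng):
        classes = {f"g{i}": RNAClass.MRNA for i in range(9)}
        edges = clique_edges(["g0", "g1", "g2", "g3"]) + \
            clique_edges(["g4", "g5", "g6"]) + [("g7", "g8")]
        net1 = make_network(edges, classes)
        shuffled = list(classes)
        rng.shuffle(shuffled)
        net2 = make_network([e[::-1] for e in reversed(edges)],
                            {g: classes[g] for g in shuffled})
        p1 = {frozenset(m) for m in mcl_cluster(net1).modules}
        p2 = {frozenset(m) for m in mcl_cluster(net2).modules}
        assert p1 == p2

    def test_partition_covers_all_nodes_disjointly(self, rng):
        fam = random_network_family(rng, n_networks=1, n_nodes=16, p_edge=0.3)
        net = next(iter(fam.values()))
        ms = mcl_cluster(net)
        all_nodes = [g for m in ms.modules for g in m]
        assert sorted(all_nodes) == sorted(net.node_set())


class TestLCFilter:
    def test_flags_and_filtering(self):
        classes = {"m1": RNAClass.MRNA, "m2": RNAClass.MRNA, "m3": RNAClass.MRNA,
                   "c1": RNAClass.CIRCRNA, "l1": RNAClass.LNCRNA}
        net = make_network([("m1", "m2"), ("c1", "m3"), ("l1", "m1")], classes)
        ms = mcl_cluster(net)
        lc = filter_lc_modules(ms)
        for mod in lc.modules:
            flags = lc.flags(mod)
            assert flags["contains_lncRNA"] or flags["contains_circRNA"]

    def test_mrna_only_module_dropped(self):
        classes = {f"m{i}": RNAClass.MRNA for i in range(3)} | \
            {"c0": RNAClass.CIRCRNA, "c1": RNAClass.CIRCRNA}
        net = make_network(clique_edges(["m0", "m1", "m2"]) + [("c0", "c1")],
                           classes)
        lc = filter_lc_modules(mcl_cluster(net))
        assert lc.modules == [("c0", "c1")]

    def test_empty_moduleset(self):
        net = make_network([("a", "b")], {"a": RNAClass.MRNA, "b": RNAClass.MRNA})
        ms = mcl_cluster(net)
        assert filter_lc_modules(ms).modules == []
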