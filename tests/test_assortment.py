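"""Weighted assortativity: analytic values, jackknife, permutation null."""

import numpy as np
import networkx as nx
import pytest

import flocknet as fn
from flocknet.config import UndefinedMetric


def two_cliques(n_per=4, w=1.0):
    nodes = [f"l{i}" for i in range(n_per)] + [f"h{i}" for i in range(n_per)]
    edges = []
    for grp in ("l", "h"):
        for i in range(n_per):
            for j in range(i + 1, n_per):
                edges.append((f"{grp}{i}", f"{grp}{j}", w))
    labels = {t: ("low" if t.startswith("l") else "high") for t in nodes}
    return nodes, edges, labels


class TestAssortativity:
    def test_perfect_within_type(self, net_factory):
        nodes, edges, labels = two_cliques()
        assert fn.assortativity(net_factory(nodes, edges), labels) == pytest.approx(1.0)

    def test_balanced_between_type_is_minus_one(self, net_factory):
        # complete balanced bipartite graph: edge-end label fractions are
        # equal, so sum(a_k^2) = 1/2 and r = -1
        nodes = [f"l{i}" for i in range(4)] + [f"h{i}" for i in range(4)]
        edges = [(f"l{i}", f"h{j}", 0.7) for i in range(4) for j in range(4)]
        labels = {t: t[0] for t in nodes}
        assert fn.assortativity(net_factory(nodes, edges), labels) == pytest.approx(-1.0)

    def test_hand_mixing_matrix_example(self, net_factory):
        # nodes a,b low and c,d high with unit edges ab, cd, bc:
        # e = [[1/3, 1/6], [1/6, 1/3]], a = (1/2, 1/2),
        # r = (2/3 - 1/2) / (1 - 1/2) = 1/3
        net = net_factory("abcd", [("a", "b", 1), ("c", "d", 1), ("b", "c", 1)])
        labels = {"a": "low", "b": "low", "c": "high", "d": "high"}
        e = fn.mixing_matrix(net, labels)
        assert np.allclose(e.to_numpy(), [[1 / 3, 1 / 6], [1 / 6, 1 / 3]])
        assert fn.assortativity(net, labels) == pytest.approx(1 / 3)

    def test_single_label_flagged(self, net_factory):
        net = net_factory("ab", [("a", "b", 1)])
        with pytest.raises(UndefinedMetric):
            fn.assortativity(net, {"a": "x", "b": "x"})

    def test_rescaling_invariance_and_range(self, net_factory):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(10)]
        edges = [
            (nodes[i], nodes[j], float(rng.uniform(0.1, 1)))
            for i in range(10)
            for j in range(i + 1, 10)
            if rng.random() < 0.4
        ]
        labels = {t: ("a" if i % 2 else "b") for i, t in enumerate(nodes)}
        net1 = net_factory(nodes, edges)
        net2 = net_factory(nodes, [(a, b, w * 0.2) for a, b, w in edges])
        r1, r2 = fn.assortativity(net1, labels), fn.assortativity(net2, labels)
        assert r1 == pytest.approx(r2)
        assert -1 <= r1 <= 1

    def test_binary_weights_match_discrete_assortativity(self, net_factory):
        rng = np.random.default_rng(12)
        for _ in range(10):
            g = nx.gnp_random_graph(12, 0.35, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() < 2:
                continue
            nodes = [f"n{i}" for i in g.nodes]
            labels = {f"n{i}": ("a" if rng.random() < 0.5 else "b") for i in g.nodes}
            if len(set(labels.values())) < 2:
                continue
            net = net_factory(nodes, [(f"n{a}", f"n{b}", 1.0) for a, b in g.edges])
            nx.set_node_attributes(g, {i: labels[f"n{i}"] for i in g.nodes}, "t")
            expected = nx.attribute_assortativity_coefficient(g, "t")
            try:
                assert fn.assortativity(net, labels) == pytest.approx(expected, abs=1e-9)
            except UndefinedMetric:
                assert np.isnan(expected)


class TestJackknife:
    def test_constant_leave_one_out_gives_zero(self, net_factory):
        nodes, edges, labels = two_cliques(n_per=4)
        assert fn.jackknife_se(net_factory(nodes, edges), labels) == pytest.approx(0.0)

    def test_hand_enumerated_value(self, net_factory):
        # leave-one-out r values for the 3-edge example: drop ab -> -1/3,
        # drop cd -> -1/3, drop bc -> 1; with r = 1/3 the squared
        # deviations are each 4/9, so se = sqrt(4/3)
        net = net_factory("abcd", [("a", "b", 1), ("c", "d", 1), ("b", "c", 1)])
        labels = {"a": "low", "b": "low", "c": "high", "d": "high"}
        assert fn.jackknife_se(net, labels) == pytest.approx(np.sqrt(4 / 3))

    def test_single_edge_flagged_undefined(self, net_factory):
        net = net_factory("abc", [("a", "b", 1)])
        assert np.isnan(fn.jackknife_se(net, {"a": "x", "b": "y", "c": "x"}))

    def test_relabeling_invariance(self, net_factory):
        edges = [("a", "b", 0.5), ("c", "d", 0.5), ("b", "c", 0.25), ("a", "d", 0.25)]
        labels = {"a": "l", "b": "l", "c": "h", "d": "h"}
        se1 = fn.jackknife_se(net_factory("abcd", edges), labels)
        swapped = [(dict(a="c", b="d", c="a", d="b")[x], dict(a="c", b="d", c="a", d="b")[y], w) for x, y, w in edges]
        se2 = fn.jackknife_se(net_factory("abcd", swapped), labels)
        assert se1 == pytest.approx(se2)


class TestPermutationNull:
    def test_null_centred_near_zero(self, gbi_factory):
        # the permutation null carries a small finite-size negative bias of
        # order -1/(n-1); on a 40-node network the mean must sit near zero
        # and inside the null band computed by an independent recount
        gbi = gbi_factory(np.random.default_rng(21), 40, 80)
        net = fn.sri_network(gbi)
        rng = np.random.default_rng(5)
        labels = {t: ("low" if rng.random() < 0.5 else "high") for t in net.nodes}
        res = fn.assortment_null(net, labels, n_perm=1000, seed=3)
        nulls = []
        rng2 = np.random.default_rng(17)
        for _ in range(1000):
            perm = {t: l for t, l in zip(net.nodes, rng2.permutation(list(labels.values())))}
            nulls.append(fn.assortativity(net, perm))
        center = np.mean(nulls)
        assert res.null_low <= center <= res.null_high
        assert abs(center) < 1 / (len(net.nodes) - 1) + 3 * np.std(nulls) / np.sqrt(len(nulls))

    def test_perfect_assortment_significant(self, net_factory):
        nodes, edges, labels = two_cliques(n_per=10)
        res = fn.assortment_null(net_factory(nodes, edges), labels, n_perm=1000, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p <= 0.01

    def test_small_n_perm_warns(self, net_factory):
        nodes, edges, labels = two_cliques(n_per=3)
        with pytest.warns(UserWarning):
            fn.assortment_null(net_factory(nodes, edges), labels, n_perm=50, seed=0)

    def test_type_one_calibration(self, gbi_factory):
        """Under random labels the permutation p is approximately uniform."""
        gbi = gbi_factory(np.random.default_rng(30), 16, 30)
        net = fn.sri_network(gbi)
        rng = np.random.default_rng(31)
        rejections = 0
        n_rep = 200
        for rep in range(n_rep):
            labels = {t: ("low" if v < 0.5 else "high") for t, v in zip(net.nodes, rng.random(len(net.nodes)))}
            if len(set(labels.values())) < 2:
                continue
            res = fn.assortment_null(net, labels, n_perm=200, seed=rep)
            if res.p <= 0.05:
                rejections += 1
        # exact binomial bounds for 200 draws at p = 0.05
        from scipy.stats import binom

        lo, hi = binom.interval(0.99, n_rep, 0.05)
        assert lo <= rejections <= hi


class TestDailyAssortment:
    def _daily(self, net_factory):
        nodes, edges, labels = two_cliques(n_per=3)
        full = net_factory(nodes, edges)
        sparse = net_factory(["l0", "l1", "h0"], [("l0", "l1", 1.0), ("l0", "h0", 0.5)])
        return [(0, "f", full), (1, "f", sparse)], labels

    def test_day_with_single_treatment_bird_skipped(self, net_factory):
        daily, labels = self._daily(net_factory)
        results, log = fn.daily_assortment(daily, labels, n_perm=120, seed=0)
        assert list(results["day"]) == [0]
        assert list(log["day"]) == [1]

    def test_all_days_skipped_is_not_an_error(self, net_factory):
        daily, labels = self._daily(net_factory)
        only_sparse = [daily[1]]
        results, log = fn.daily_assortment(only_sparse, labels, n_perm=120, seed=0)
        assert len(results) == 0 and len(log) == 1
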