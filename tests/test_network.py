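import numpy as np
import pandas as pd
import pytest

from brackish.network import (
    CorrelationNetwork,
    build_network,
    detect_modules,
    erdos_renyi_ensemble,
    filter_for_network,
    natural_connectivity,
    network_dissimilarity,
    robustness_curve,
    sparcc,
    sparcc_pvalues,
    topology,
    zi_pi,
    _degree_distribution_verdict,
)
from brackish.otu_table import OtuTable
from brackish.synthetic import (
    NeutralSimConfig,
    implant_correlations,
    make_source_pool,
    simulate_neutral_series,
)


def _net(nodes, pairs):
    return CorrelationNetwork(
        tuple(nodes), tuple((u, v, 0.9, 0.001) for u, v in pairs))


def _clique(prefix, k):
    nodes = [f"{prefix}{i}" for i in range(k)]
    pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    return nodes, pairs


@pytest.fixture(scope="module")
def implanted():
    pool = make_source_pool(50, 1.0, seed=3)
    cfg = NeutralSimConfig(S=50, N=5000, m=0.3, n_samples=120, seed=4)
    t = simulate_neutral_series(pool, cfg)
    top = [pool.otu_ids[i] for i in np.argsort(-pool.p)[:10]]
    pairs = [(top[2 * i], top[2 * i + 1], -1 if i == 2 else 1) for i in range(5)]
    return implant_correlations(t, pairs, rho=0.9, seed=5), pairs, t


class TestFilterForNetwork:
    def test_thresholds(self):
        n = 25
        counts = np.zeros((n, 3), dtype=int)
        counts[:, 0] = 100                      # abundant anchor
        counts[:19, 1] = 10                     # occupancy 19, total 190 -> removed
        counts[:19, 2] = np.r_[[132], np.ones(18, dtype=int)]  # total 150, occ 19...
        counts[19:, 2] = 0
        t = OtuTable(tuple(f"s{i}" for i in range(n)), ("anchor", "rare", "lowtot"),
                     counts)
        out = filter_for_network(t, 20, 200)
        assert "rare" not in out.otu_ids
        # occupancy 19 < 20 but conjunctive requires total < 200 too; 150 < 200 -> removed
        assert "lowtot" not in out.otu_ids

    def test_retained_when_one_condition_fails(self):
        n = 60
        counts = np.zeros((n, 2), dtype=int)
        counts[:, 0] = 100
        counts[:50, 1] = 3   # occupancy 50 >= 20, total 150 < 200
        t = OtuTable(tuple(f"s{i}" for i in range(n)), ("anchor", "wide"), counts)
        out = filter_for_network(t, 20, 200)
        assert "wide" in out.otu_ids

    def test_zero_thresholds_identity(self, neutral_table):
        out = filter_for_network(neutral_table, 0, 0)
        assert out.otu_ids == neutral_table.otu_ids


class TestSparcc:
    def test_independent_data_near_zero(self):
        pool = make_source_pool(50, 0.8, seed=10)
        cfg = NeutralSimConfig(S=50, N=5000, m=1.0, n_samples=200, seed=11)
        t = simulate_neutral_series(pool, cfg)
        r = sparcc(t, seed=12).to_numpy()
        iu = np.triu_indices_from(r, k=1)
        assert np.abs(r[iu]).mean() < 0.1

    def test_recovers_implanted_pair(self, implanted):
        t2, pairs, _ = implanted
        r = sparcc(t2, seed=6)
        u, v, sign = pairs[0]
        assert abs(r.loc[u, v]) > 0.6
        assert np.sign(r.loc[pairs[2][0], pairs[2][1]]) == -1

    def test_sample_order_invariance(self, implanted):
        from brackish.otu_table import subset

        t2, _, _ = implanted
        perm = list(t2.sample_ids[::-1])
        r1 = sparcc(t2, n_inner_iter=3, seed=7)
        r2 = sparcc(subset(t2, sample_ids=perm), n_inner_iter=3, seed=7)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_symmetric_unit_diagonal(self, implanted):
        t2, _, _ = implanted
        r = sparcc(t2, n_inner_iter=3, seed=8).to_numpy()
        np.testing.assert_allclose(r, r.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r), 1.0)
        assert (np.abs(r) <= 1.0 + 1e-12).all()

    def test_too_small_rejected(self):
        t = OtuTable(("s1", "s2"), tuple("abcdefghij"),
                     np.ones((2, 10), dtype=int))
        with pytest.raises(ValueError):
            sparcc(t)


class TestSparccPvalues:
    def test_implanted_pair_at_floor_and_null_uniformish(self, implanted):
        t2, pairs, _ = implanted
        r = sparcc(t2, seed=6)
        p = sparcc_pvalues(t2, r, n_boot=40, seed=9)
        u, v, _ = pairs[0]
        assert p.loc[u, v] == pytest.approx(1 / 41)
        pm = p.to_numpy()
        np.testing.assert_allclose(pm, pm.T, atol=1e-12)
        assert (pm >= 1 / 41 - 1e-12).all()
        # p-values for non-implanted pairs should spread over (0, 1]
        imp = {x for pr in pairs for x in pr[:2]}
        ids = list(p.index)
        mask = np.array([[a not in imp and b not in imp for b in ids] for a in ids])
        iu = np.triu_indices_from(pm, k=1)
        null_ps = pm[iu][mask[iu]]
        from scipy.stats import kstest

        assert kstest(null_ps, "uniform").statistic < 0.2

    def test_small_n_boot_rejected(self, implanted):
        t2, _, _ = implanted
        r = sparcc(t2, n_inner_iter=2, seed=1)
        with pytest.raises(ValueError):
            sparcc_pvalues(t2, r, n_boot=5)


class TestBuildNetwork:
    def _mats(self, r12, p12):
        ids = ["a", "b", "c"]
        r = pd.DataFrame(np.eye(3), index=ids, columns=ids)
        p = pd.DataFrame(np.ones((3, 3)), index=ids, columns=ids)
        r.loc["a", "b"] = r.loc["b", "a"] = r12
        p.loc["a", "b"] = p.loc["b", "a"] = p12
        return r, p

    def test_edge_thresholds(self):
        net = build_network(*self._mats(0.61, 0.005))
        assert net.edge_set() == {("a", "b")}
        net = build_network(*self._mats(0.61, 0.02))
        assert net.n_edges == 0
        net = build_network(*self._mats(0.60, 0.005))
        assert net.n_edges == 0  # strict inequality on |r|

    def test_impossible_threshold_empty(self):
        net = build_network(*self._mats(0.99, 0.001), r_threshold=1.0)
        assert net.n_edges == 0

    def test_edges_satisfy_thresholds(self, implanted):
        t2, _, _ = implanted
        r = sparcc(t2, seed=6)
        p = sparcc_pvalues(t2, r, n_boot=40, seed=9)
        net = build_network(r, p)
        for u, v, rv, pv in net.edges:
            assert abs(rv) > 0.6 and pv < 0.01


class TestTopology:
    def test_triangle(self):
        net = _net("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        topo = topology(net)
        assert topo.avg_clustering == pytest.approx(1.0)
        assert topo.avg_path_length == pytest.approx(1.0)
        assert topo.avg_degree == pytest.approx(2.0)

    def test_three_path(self):
        net = _net("abc", [("a", "b"), ("b", "c")])
        topo = topology(net)
        assert topo.avg_clustering == pytest.approx(0.0)
        assert topo.avg_path_length == pytest.approx(4 / 3)

    def test_degree_verdicts(self):
        import networkx as nx

        pl_ok = po_ok = 0
        for s in range(10):
            ba = nx.barabasi_albert_graph(250, 3, seed=s)
            er = nx.gnm_random_graph(250, 750, seed=s)
            deg_ba = np.array([d for _, d in ba.degree()])
            deg_er = np.array([d for _, d in er.degree()])
            pl_ok += _degree_distribution_verdict(deg_ba)["verdict"] == "power-law"
            po_ok += _degree_distribution_verdict(deg_er)["verdict"] == "poisson"
        assert pl_ok >= 9
        assert po_ok >= 9


class TestErdosRenyi:
    def test_exact_edge_count_and_single_member(self):
        ens = erdos_renyi_ensemble(15, 30, n_random=1, seed=1)
        assert len(ens.metrics) == 1
        assert ens.n_edges == 30

    def test_modular_graph_exceeds_null_clustering(self):
        n1, p1 = _clique("a", 6)
        n2, p2 = _clique("b", 6)
        net = _net(n1 + n2, p1 + p2 + [("a0", "b0")])
        topo = topology(net)
        ens = erdos_renyi_ensemble(net.n_nodes, net.n_edges, n_random=200, seed=2)
        q = ens.quantile_of("avg_clustering", topo.avg_clustering)
        assert q > 0.975

    def test_too_many_edges_rejected(self):
        with pytest.raises(ValueError):
            erdos_renyi_ensemble(4, 7)


class TestModulesAndRoles:
    def test_two_cliques_recovered(self):
        n1, p1 = _clique("a", 5)
        n2, p2 = _clique("b", 5)
        net = _net(n1 + n2, p1 + p2 + [("a0", "b0")])
        part = detect_modules(net)
        assert len(set(part.values())) == 2
        assert len({part[n] for n in n1}) == 1
        assert len({part[n] for n in n2}) == 1

    def test_complete_graph_single_module(self):
        nodes, pairs = _clique("k", 6)
        part = detect_modules(_net(nodes, pairs))
        assert len(set(part.values())) == 1

    def test_louvain_seed_deterministic(self):
        n1, p1 = _clique("a", 6)
        n2, p2 = _clique("b", 6)
        net = _net(n1 + n2, p1 + p2 + [("a0", "b0")])
        a = detect_modules(net, method="louvain", seed=5)
        b = detect_modules(net, method="louvain", seed=5)
        assert a == b

    def test_participation_zero_within_module(self):
        nodes, pairs = _clique("k", 5)
        net = _net(nodes, pairs)
        roles = zi_pi(net, detect_modules(net))
        assert all(r.pi == pytest.approx(0.0) for r in roles)

    def test_even_split_participation(self):
        # hub with one edge into each of 4 modules of a 4-clique each
        nodes, pairs = [], []
        for m in range(4):
            n, p = _clique(f"m{m}_", 4)
            nodes += n
            pairs += p
        nodes.append("hub")
        pairs += [("hub", f"m{m}_0") for m in range(4)]
        net = _net(nodes, pairs)
        part = {n: int(n[1]) for n in net.nodes if n != "hub"}
        part["hub"] = 0
        roles = {r.otu_id: r for r in zi_pi(net, part)}
        assert roles["hub"].pi == pytest.approx(0.75)
        assert roles["hub"].category == "connector"

    def test_star_hub_is_module_hub(self):
        nodes = [f"n{i}" for i in range(20)]
        net = _net(nodes, [("n0", x) for x in nodes[1:]])
        part = dict.fromkeys(nodes, 0)
        roles = {r.otu_id: r for r in zi_pi(net, part)}
        assert roles["n0"].zi > 2.5
        assert roles["n0"].pi == pytest.approx(0.0)
        assert roles["n0"].category == "module hub"

    def test_relabelling_invariance(self):
        n1, p1 = _clique("a", 5)
        net1 = _net(n1, p1 + [])
        mapping = {n: f"x{n}" for n in n1}
        net2 = _net([mapping[n] for n in n1],
                    [(mapping[u], mapping[v]) for u, v in p1])
        r1 = {r.otu_id: r.category for r in zi_pi(net1, detect_modules(net1))}
        r2 = {r.otu_id: r.category for r in zi_pi(net2, detect_modules(net2))}
        assert {mapping[k]: v for k, v in r1.items()} == r2

    def test_partition_must_cover(self):
        nodes, pairs = _clique("k", 4)
        net = _net(nodes, pairs)
        with pytest.raises(ValueError):
            zi_pi(net, {"k0": 0})


class TestDissimilarity:
    def test_identical_zero(self):
        net = _net("abc", [("a", "b"), ("b", "c")])
        assert network_dissimilarity(net, net) == pytest.approx(0.0)

    def test_disjoint_one(self):
        n1 = _net("ab", [("a", "b")])
        n2 = _net("cd", [("c", "d")])
        assert network_dissimilarity(n1, n2) == pytest.approx(1.0)

    def test_hand_computed_third(self):
        # a = 2 shared, b = 1, c = 1 -> 4/3 - 1 = 1/3
        nB = _net("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        nC = _net("abcd", [("a", "b"), ("b", "c"), ("a", "d")])
        assert network_dissimilarity(nB, nC) == pytest.approx(1 / 3)

    def test_symmetry(self):
        nB = _net("abcd", [("a", "b"), ("b", "c"), ("c", "d")])
        nC = _net("abcd", [("a", "b"), ("a", "d")])
        assert network_dissimilarity(nB, nC) == pytest.approx(
            network_dissimilarity(nC, nB))

    def test_both_empty_undefined(self):
        n1 = CorrelationNetwork(("a",), ())
        with pytest.raises(ValueError):
            network_dissimilarity(n1, n1)


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        assert natural_connectivity(np.zeros((7, 7))) == pytest.approx(0.0)

    def test_k3_closed_form(self):
        net = _net("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        expected = np.log((np.e**2 + 2 / np.e) / 3)
        assert natural_connectivity(net) == pytest.approx(expected)

    def test_edge_addition_monotone(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            a = (rng.random((n, n)) < 0.3).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            before = natural_connectivity(a)
            empty = np.argwhere(np.triu(a == 0, 1))
            empty = [e for e in empty if e[0] != e[1]]
            if not empty:
                continue
            i, j = empty[int(rng.integers(len(empty)))]
            a[i, j] = a[j, i] = 1.0
            assert natural_connectivity(a) >= before - 1e-12

    def test_disjoint_union_composition(self):
        # eigenvalues of a disjoint union are the union of component spectra
        rng = np.random.default_rng(12)
        a = (rng.random((20, 20)) < 0.2).astype(float)
        a = np.triu(a, 1); a = a + a.T
        b = (rng.random((30, 30)) < 0.3).astype(float)
        b = np.triu(b, 1); b = b + b.T
        union = np.zeros((50, 50))
        union[:20, :20] = a
        union[20:, 20:] = b
        la = np.linalg.eigvalsh(a)
        lb = np.linalg.eigvalsh(b)
        from scipy.special import logsumexp

        expected = logsumexp(np.r_[la, lb]) - np.log(50)
        assert natural_connectivity(union) == pytest.approx(expected)


class TestRobustness:
    def test_fraction_zero_is_intact_value(self):
        nodes, pairs = _clique("k", 10)
        net = _net(nodes, pairs)
        curve = robustness_curve(net, [0.0, 0.3], n_reps=20, seed=1)
        assert curve.mean[0] == pytest.approx(natural_connectivity(net))
        assert curve.sd[0] == 0.0

    def test_complete_beats_star(self):
        n = 30
        nodes = [f"n{i}" for i in range(n)]
        comp = _net(nodes, [(nodes[i], nodes[j])
                            for i in range(n) for j in range(i + 1, n)])
        star = _net(nodes, [(nodes[0], x) for x in nodes[1:]])
        fr = np.arange(0.2, 0.81, 0.1)
        c1 = robustness_curve(comp, fr, n_reps=50, seed=2)
        c2 = robustness_curve(star, fr, n_reps=50, seed=2)
        assert (c1.mean > c2.mean).all()

    def test_seed_reproducible(self):
        nodes, pairs = _clique("k", 12)
        net = _net(nodes, pairs)
        a = robustness_curve(net, [0.2, 0.5], n_reps=10, seed=3)
        b = robustness_curve(net, [0.2, 0.5], n_reps=10, seed=3)
        np.testing.assert_array_equal(a.mean, b.mean)

    def test_removing_everything_rejected(self):
        nodes, pairs = _clique("k", 4)
        with pytest.raises(ValueError):
            robustness_curve(_net(nodes, pairs), [0.99], n_reps=2, seed=1)
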