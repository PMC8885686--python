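import itertools

import networkx as nx
import numpy as np
import pytest

from raretax.datatypes import OtuTable
from raretax.errors import ComputationError, ParameterError
from raretax.network import (
    build_fraction_network,
    build_network,
    detect_modules,
    random_network_ensemble,
    spearman_matrix,
    topology_metrics,
    zipi_roles,
)
from raretax.partition import classify_taxa


def table_from(counts):
    counts = np.asarray(counts)
    return OtuTable(tuple(f"s{i}" for i in range(counts.shape[0])),
                    tuple(f"o{j}" for j in range(counts.shape[1])),
                    counts)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def bfs_distances(net, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in net.neighbors(u):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def brute_path_stats(net):
    total, pairs, diam = 0.0, 0, 0
    for u in net.nodes:
        d = bfs_distances(net, u)
        for v, dv in d.items():
            if v != u:
                total += dv
                pairs += 1
                diam = max(diam, dv)
    return (total / pairs if pairs else 0.0), float(diam)


def brute_clustering(net):
    vals = []
    for u in net.nodes:
        nbrs = list(net.neighbors(u))
        k = len(nbrs)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2)
                    if net.has_edge(a, b))
        vals.append(2 * links / (k * (k - 1)))
    return float(np.mean(vals))


def modularity_formula(net, modules):
    m = net.number_of_edges()
    by = {}
    for n_, c in modules.items():
        by.setdefault(c, set()).add(n_)
    q = 0.0
    for nodes in by.values():
        e_c = sum(1 for a, b in net.edges
                  if a in nodes and b in nodes)
        deg_c = sum(net.degree(n_) for n_ in nodes)
        q += e_c / m - (deg_c / (2 * m)) ** 2
    return q


# ---------------------------------------------------------------------------
# Spearman screening
# ---------------------------------------------------------------------------

class TestSpearman:
    def test_monotone_and_antimonotone(self):
        x = np.arange(1, 9)
        counts = np.column_stack([x, x ** 2, 9 - x, np.full(8, 3)])
        counts[0, 3] += 1  # break constancy guard only mildly
        t = table_from(counts)
        rho, p, ids = spearman_matrix(t, min_prevalence=0.0)
        i = {o: k for k, o in enumerate(ids)}
        assert rho[i["o0"], i["o1"]] == pytest.approx(1.0)
        assert rho[i["o0"], i["o2"]] == pytest.approx(-1.0)

    def test_tied_ranks_hand_case(self):
        # x = (1,2,2,4,5) -> ranks (1, 2.5, 2.5, 4, 5); y monotone
        x = np.array([1, 2, 2, 4, 5])
        y = np.array([2, 4, 6, 8, 10])
        rx = np.array([1, 2.5, 2.5, 4, 5])
        ry = np.array([1, 2, 3, 4, 5])
        expected = np.corrcoef(rx, ry)[0, 1]
        t = table_from(np.column_stack([x, y]))
        rho, _, ids = spearman_matrix(t, min_prevalence=0.0)
        assert rho[0, 1] == pytest.approx(expected)

    def test_constant_otu_flagged_nan(self):
        counts = np.column_stack([np.arange(1, 7), np.full(6, 5),
                                  np.arange(6, 0, -1)])
        t = table_from(counts)
        rho, p, ids = spearman_matrix(t, min_prevalence=0.0)
        assert np.isnan(rho[0, 1]) and np.isnan(p[0, 1])
        assert np.isfinite(rho[0, 2])

    def test_prevalence_filter(self):
        counts = np.zeros((9, 2), int)
        counts[:, 0] = np.arange(1, 10)
        counts[0, 1] = 4  # present in 1/9 samples only
        counts[1, 1] = 2
        t = table_from(counts)
        with pytest.raises(ComputationError):
            spearman_matrix(t, min_prevalence=1 / 3)


class TestBuildNetwork:
    def test_zero_correlations_empty_network(self):
        n = 4
        rho = np.zeros((n, n))
        p = np.ones((n, n))
        net = build_network(rho, p, [f"o{i}" for i in range(n)])
        assert net.number_of_edges() == 0

    def test_boundary_rho_inclusive(self):
        rho = np.array([[1.0, 0.6], [0.6, 1.0]])
        p = np.array([[0.0, 1e-6], [1e-6, 0.0]])
        net = build_network(rho, p, ["a", "b"])
        assert net.has_edge("a", "b")
        rho2 = rho.copy()
        rho2[0, 1] = rho2[1, 0] = 0.599
        assert build_network(rho2, p, ["a", "b"]).number_of_edges() == 0

    def test_sign_retained(self):
        rho = np.array([[1, -0.9, 0.9],
                        [-0.9, 1, 0.0],
                        [0.9, 0.0, 1.0]])
        p = np.full((3, 3), 1e-9)
        net = build_network(rho, p, ["a", "b", "c"])
        assert net["a"]["b"]["sign"] == -1
        assert net["a"]["c"]["sign"] == 1

    def test_planted_block_recovery_single_seed(self):
        rng = np.random.default_rng(0)
        t = planted_block_table(rng)
        classes = classify_taxa(t)
        net = build_fraction_network(t, classes, min_prevalence=0.0)
        block = {f"o{i}" for i in range(10)}
        hits = sum(1 for a, b in itertools.combinations(sorted(block), 2)
                   if net.has_edge(a, b))
        assert hits / 45 >= 0.8


def planted_block_table(rng, n_block=10, n_noise=50, n_samples=30,
                        rho=0.9):
    """Counts with a mutually correlated OTU block amid independent OTUs."""
    z = rng.normal(size=n_samples)
    block = (np.sqrt(rho) * z[:, None]
             + np.sqrt(1 - rho) * rng.normal(size=(n_samples, n_block)))
    noise = rng.normal(size=(n_samples, n_noise))
    latent = np.column_stack([block, noise])
    counts = np.floor(np.exp(latent) * 50).astype(int) + 1
    return table_from(counts)


class TestTopology:
    def test_triangle_closed_forms(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        topo = topology_metrics(net, seed=0)
        assert topo.clustering_coefficient == 1.0
        assert topo.avg_path_length == 1.0
        assert topo.diameter == 1.0
        assert topo.avg_degree == 2.0
        assert topo.density == 1.0

    def test_three_node_path(self):
        net = nx.Graph([("a", "b"), ("b", "c")])
        topo = topology_metrics(net, seed=0)
        assert topo.avg_path_length == pytest.approx(4 / 3)
        assert topo.diameter == 2.0

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(1)
        for _ in range(40):
            n = int(rng.integers(3, 9))
            p_edge = rng.uniform(0.2, 0.9)
            net = nx.gnp_random_graph(n, p_edge,
                                      seed=int(rng.integers(2 ** 31)))
            net.remove_nodes_from(list(nx.isolates(net)))
            if net.number_of_nodes() == 0:
                continue
            topo = topology_metrics(net, seed=0)
            gd, diam = brute_path_stats(net)
            assert topo.avg_path_length == pytest.approx(gd)
            assert topo.diameter == pytest.approx(diam)
            assert topo.clustering_coefficient == pytest.approx(
                brute_clustering(net))
            assert topo.avg_degree == pytest.approx(
                2 * net.number_of_edges() / net.number_of_nodes())

    def test_empty_network_is_error(self):
        with pytest.raises(ComputationError):
            topology_metrics(nx.Graph(), seed=0)


class TestModules:
    def test_two_triangles_q_half(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c"),
                        ("x", "y"), ("y", "z"), ("x", "z")])
        modules, q = detect_modules(net, seed=0)
        assert len(set(modules.values())) == 2
        assert q == pytest.approx(0.5)
        assert q == pytest.approx(modularity_formula(net, modules))

    def test_complete_graph_single_module(self):
        net = nx.complete_graph(5)
        modules, q = detect_modules(net, seed=0)
        assert len(set(modules.values())) == 1
        assert q == pytest.approx(0.0)

    def test_beats_or_matches_planted_partition(self):
        rng = np.random.default_rng(3)
        for rep in range(5):
            net = nx.planted_partition_graph(4, 15, 0.5, 0.02,
                                             seed=int(rng.integers(2**31)))
            net = nx.Graph(net)  # drop graph-type metadata
            planted = {n_: n_ // 15 for n_ in net.nodes}
            modules, q = detect_modules(net, seed=rep)
            assert q >= modularity_formula(net, planted) - 1e-9


class TestRandomEnsemble:
    def test_degree_sequence_preserved(self):
        rng = np.random.default_rng(5)
        net = nx.gnp_random_graph(20, 0.25, seed=2)
        net.remove_nodes_from(list(nx.isolates(net)))
        before = sorted(dict(net.degree()).values())
        # rewire one replicate by hand through the same primitive
        h = nx.Graph(net.edges())
        nx.double_edge_swap(h, nswap=10 * h.number_of_edges(),
                            max_tries=10 ** 5, seed=1)
        assert sorted(dict(h.degree()).values()) == before

    def test_structureless_input_self_consistent(self):
        """Degree-preserving rewiring of an ER graph leaves avgCC within
        the ensemble spread of the input."""
        net = nx.gnp_random_graph(40, 0.15, seed=7)
        net.remove_nodes_from(list(nx.isolates(net)))
        stats = random_network_ensemble(net, n_random=30, seed=0)
        cc_in = nx.average_clustering(net)
        mu, sd = stats.loc["avgCC", "mean"], stats.loc["avgCC", "sd"]
        assert abs(cc_in - mu) <= 3 * max(sd, 1e-6)

    def test_modular_input_exceeds_ensemble(self):
        net = nx.Graph(nx.planted_partition_graph(4, 15, 0.5, 0.02,
                                                  seed=11))
        _, q_emp = detect_modules(net, seed=0)
        stats = random_network_ensemble(net, n_random=25, seed=1)
        assert q_emp > stats.loc["modularity", "mean"] \
            + 2 * stats.loc["modularity", "sd"]

    def test_too_small_graph_rejected(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(ParameterError):
            random_network_ensemble(net, n_random=3, seed=0)


class TestZiPi:
    def build(self, edges, modules):
        net = nx.Graph(edges)
        nx.set_node_attributes(net, modules, "module")
        return net

    def test_all_internal_edges_pi_zero(self):
        net = self.build([("a", "b"), ("a", "c")],
                         {"a": 0, "b": 0, "c": 0})
        roles = zipi_roles(net)
        assert (roles["pi"] == 0).all()

    def test_even_split_pi_half(self):
        edges = [("hub", x) for x in ("a1", "a2", "b1", "b2")]
        modules = {"hub": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = zipi_roles(self.build(edges, modules))
        assert roles.loc["hub", "pi"] == pytest.approx(0.5)

    def test_uniform_module_all_zi_zero_peripheral(self):
        net = self.build([("a", "b"), ("b", "c"), ("a", "c")],
                         {"a": 0, "b": 0, "c": 0})
        roles = zipi_roles(net)
        assert (roles["zi"] == 0).all()
        assert (roles["role"] == "peripheral").all()

    def test_connector_threshold(self):
        # links split evenly over three modules: Pi = 1 - 3*(1/3)^2 = 2/3
        edges = [("c", "m1"), ("c", "x1"), ("c", "y1")]
        modules = {"c": 0, "m1": 0, "x1": 1, "y1": 2}
        roles = zipi_roles(self.build(edges, modules))
        assert roles.loc["c", "pi"] == pytest.approx(2 / 3)
        assert roles.loc["c", "role"] == "connector"
        # 2/4 outside one module: Pi = 1 - (1/4 + 1/4) = 0.5 -> peripheral
        edges2 = [("d", "m1"), ("d", "m2"), ("d", "x1"), ("d", "x2")]
        modules2 = {"d": 0, "m1": 0, "m2": 0, "x1": 1, "x2": 1}
        roles2 = zipi_roles(self.build(edges2, modules2))
        assert roles2.loc["d", "pi"] == pytest.approx(0.5)
        assert roles2.loc["d", "role"] == "peripheral"

    def test_requires_modules(self):
        with pytest.raises(ParameterError):
            zipi_roles(nx.Graph([("a", "b")]))


def test_fraction_networks_subset_of_candidates(small_dataset):
    """Nodes of per-fraction networks come from that fraction's OTUs."""
    t = small_dataset.table
    classes = classify_taxa(t)
    for fraction in ("abundant", "whole"):
        net = build_fraction_network(t, classes, fraction=fraction,
                                     min_prevalence=1 / 3)
        allowed = set(classes.otus(fraction))
        assert set(net.nodes) <= allowed
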