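"""Co-occurrence network inference and topology.

Edges are strong, FDR-significant Spearman correlations between OTU
abundance profiles across samples (|rho| >= 0.6 and BH-adjusted
p <= 0.01 by default, both thresholds inclusive). Network-level topology
follows the usual co-occurrence conventions: clustering coefficient as
the mean local transitivity (degree-<2 nodes contribute 0), average path
length and diameter over within-component pairs, modularity from greedy
(Louvain) module detection on the unweighted, unsigned graph. Node roles
come from the within-module degree z-score (Zi) and the among-module
participation coefficient (Pi) with the conventional 2.5 / 0.62 cutoffs.
"""
from __future__ import annotations

import random
import warnings
from dataclasses import asdict, dataclass

import igraph as ig
import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .beta import bh_adjust
from .datatypes import AbundanceClassMap, OtuTable
from .errors import ComputationError, ParameterError

DEFAULT_RHO_MIN = 0.6
DEFAULT_P_MAX = 0.01
ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62


# ---------------------------------------------------------------------------
# Correlation screening
# ---------------------------------------------------------------------------

def spearman_matrix(table: OtuTable, min_prevalence: float = 1 / 3):
    """All pairwise Spearman correlations among sufficiently prevalent OTUs.

    OTUs present in fewer than ``min_prevalence`` of the samples are
    excluded before testing (rank correlation on mostly-zero vectors is
    unstable). Returns ``(rho, p, otu_ids)``; constant OTU vectors yield
    NaN entries, which downstream edge construction skips.
    """
    counts = table.counts
    prevalence = (counts > 0).mean(axis=0)
    keep = prevalence >= min_prevalence
    ids = [o for o, k in zip(table.otu_ids, keep) if k]
    x = counts[:, keep].astype(float)
    if len(ids) < 2:
        raise ComputationError(
            "fewer than 2 OTUs pass the prevalence filter")
    # constant vectors have no defined rank correlation; scipy collapses
    # the whole result to NaN when one is present, so exclude them first
    # and mark their pairs NaN
    variable = x.std(axis=0) > 0
    n = len(ids)
    rho = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    idx = np.flatnonzero(variable)
    if len(idx) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_sub, p_sub = scipy.stats.spearmanr(x[:, idx])
        if np.ndim(r_sub) == 0:  # scipy returns scalars for two columns
            r_sub = np.array([[1.0, float(r_sub)], [float(r_sub), 1.0]])
            p_sub = np.array([[0.0, float(p_sub)], [float(p_sub), 0.0]])
        rho[np.ix_(idx, idx)] = r_sub
        p[np.ix_(idx, idx)] = p_sub
    return rho, p, ids


def build_network(rho: np.ndarray, p: np.ndarray, otu_ids,
                  rho_min: float = DEFAULT_RHO_MIN,
                  p_max: float = DEFAULT_P_MAX,
                  classes: AbundanceClassMap | None = None) -> nx.Graph:
    """Threshold a correlation matrix into an undirected network.

    BH-FDR adjustment runs across all tested pairs (the upper triangle,
    NaN pairs excluded); an edge is kept iff ``|rho| >= rho_min`` and
    adjusted ``p <= p_max``. The correlation sign is retained as an edge
    attribute; isolated nodes are dropped.
    """
    rho = np.asarray(rho, float)
    p = np.asarray(p, float)
    otu_ids = list(otu_ids)
    n = len(otu_ids)
    if rho.shape != (n, n) or p.shape != (n, n):
        raise ParameterError("rho/p must be square matrices over otu_ids")
    iu = np.triu_indices(n, 1)
    pvals = p[iu]
    rhos = rho[iu]
    tested = np.isfinite(pvals) & np.isfinite(rhos)
    q = np.full(len(pvals), np.nan)
    q[tested] = bh_adjust(pvals[tested])
    keep = tested & (np.abs(rhos) >= rho_min) & (q <= p_max)
    net = nx.Graph()
    label = (classes.frame["label"] if classes is not None else None)
    for k in np.flatnonzero(keep):
        a = otu_ids[iu[0][k]]
        b = otu_ids[iu[1][k]]
        net.add_edge(a, b, rho=float(rhos[k]), p_adj=float(q[k]),
                     sign=1 if rhos[k] > 0 else -1)
    if label is not None:
        for node in net.nodes:
            if node in label.index:
                net.nodes[node]["abundance_class"] = str(label[node])
    return net


# ---------------------------------------------------------------------------
# Module detection and topology
# ---------------------------------------------------------------------------

def _to_igraph(net: nx.Graph):
    nodes = list(net.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def _louvain(graph: ig.Graph, seed: int):
    """Seeded multilevel (Louvain) partition of an igraph graph."""
    ig.set_random_number_generator(random.Random(int(seed)))
    clustering = graph.community_multilevel()
    return clustering.membership, float(
        graph.modularity(clustering.membership))


def detect_modules(net: nx.Graph, seed: int = 0):
    """Louvain module detection on the unweighted, unsigned graph.

    Returns ``(modules, q)`` where ``modules`` maps node -> module id
    (also stored as the ``module`` node attribute) and ``q`` is the
    Newman-Girvan modularity of the partition. The optimization runs on
    igraph's C multilevel implementation with a seeded generator.
    """
    if net.number_of_nodes() == 0:
        raise ComputationError("cannot partition an empty network")
    graph, nodes = _to_igraph(net)
    if net.number_of_edges() == 0:
        modules = {n: i for i, n in enumerate(nodes)}
        nx.set_node_attributes(net, modules, "module")
        return modules, 0.0
    membership, q = _louvain(graph, seed)
    # renumber module ids deterministically by each module's first node
    first = {}
    for node, mid in zip(nodes, membership):
        first.setdefault(mid, node)
    order = sorted(first, key=lambda mid: str(first[mid]))
    renumber = {mid: k for k, mid in enumerate(order)}
    modules = {node: renumber[mid] for node, mid in zip(nodes, membership)}
    nx.set_node_attributes(net, modules, "module")
    return modules, q


@dataclass
class TopologySummary:
    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    clustering_coefficient: float
    avg_path_length: float
    diameter: float
    modularity: float
    n_modules: int
    n_positive_edges: int
    n_negative_edges: int

    # pMEN-style aliases
    @property
    def GD(self) -> float:
        return self.avg_path_length

    @property
    def avgK(self) -> float:
        return self.avg_degree

    @property
    def avgCC(self) -> float:
        return self.clustering_coefficient

    def to_dict(self) -> dict:
        d = asdict(self)
        d.update(GD=self.GD, avgK=self.avgK, avgCC=self.avgCC)
        return d


def _path_stats_ig(graph: ig.Graph):
    """Mean geodesic distance and diameter over within-component pairs."""
    if graph.vcount() < 2 or graph.ecount() == 0:
        return 0.0, 0.0
    return (float(graph.average_path_length(directed=False, unconn=True)),
            float(graph.diameter(directed=False, unconn=True)))


def _path_stats(net: nx.Graph):
    graph, _ = _to_igraph(net)
    return _path_stats_ig(graph)


def _avg_clustering_ig(graph: ig.Graph) -> float:
    """Mean local transitivity; degree-<2 nodes contribute 0."""
    if graph.vcount() == 0:
        return 0.0
    return float(np.mean(graph.transitivity_local_undirected(mode="zero")))


def topology_metrics(net: nx.Graph, seed: int = 0) -> TopologySummary:
    """Network-level topology of a co-occurrence network."""
    n = net.number_of_nodes()
    m = net.number_of_edges()
    if n == 0:
        raise ComputationError("empty network has no topology")
    modules, q = detect_modules(net, seed=seed)
    graph, _ = _to_igraph(net)
    gd, diam = _path_stats_ig(graph)
    signs = [d.get("sign", 0) for _, _, d in net.edges(data=True)]
    return TopologySummary(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        density=2.0 * m / (n * (n - 1)) if n > 1 else 0.0,
        clustering_coefficient=_avg_clustering_ig(graph),
        avg_path_length=gd,
        diameter=diam,
        modularity=q,
        n_modules=len(set(modules.values())),
        n_positive_edges=sum(1 for s in signs if s > 0),
        n_negative_edges=sum(1 for s in signs if s < 0),
    )


# ---------------------------------------------------------------------------
# Random-network baseline
# ---------------------------------------------------------------------------

def random_network_ensemble(net: nx.Graph, n_random: int = 100,
                            seed: int = 0,
                            swaps_per_edge: int = 10) -> pd.DataFrame:
    """Degree-preserving rewired baseline (mean/sd of GD, avgCC, modularity).

    Each replicate applies ``swaps_per_edge * n_edges`` successful double
    edge swaps (multi-edges and self-loops rejected), preserving every
    node's degree. Returns a one-row-per-metric frame with columns
    ``mean`` and ``sd``.
    """
    m = net.number_of_edges()
    if m < 2 or net.number_of_nodes() < 4:
        raise ParameterError(
            "network too small for degree-preserving rewiring")
    base, _ = _to_igraph(net)
    ss = np.random.SeedSequence(seed)
    records = {"GD": [], "avgCC": [], "modularity": []}
    for child in ss.spawn(n_random):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        h = base.copy()
        ig.set_random_number_generator(random.Random(rep_seed))
        h.rewire(n=swaps_per_edge * m, mode="simple")
        gd, _ = _path_stats_ig(h)
        _, q = _louvain(h, rep_seed)
        records["GD"].append(gd)
        records["avgCC"].append(_avg_clustering_ig(h))
        records["modularity"].append(q)
    rows = [{"metric": k, "mean": float(np.mean(v)),
             "sd": float(np.std(v, ddof=1))}
            for k, v in records.items()]
    return pd.DataFrame(rows).set_index("metric")


# ---------------------------------------------------------------------------
# Zi-Pi node roles
# ---------------------------------------------------------------------------

def zipi_roles(net: nx.Graph, zi_threshold: float = ZI_THRESHOLD,
               pi_threshold: float = PI_THRESHOLD) -> pd.DataFrame:
    """Within-module connectivity (Zi) and participation (Pi) per node.

    ``Zi`` is the z-score of a node's within-module degree relative to
    the other members of its module (0 when the module's spread is 0);
    ``Pi = 1 - sum_s (k_is / k_i)^2`` over modules ``s``. Roles:
    module hub (Zi >= 2.5, Pi < 0.62), connector (Zi < 2.5, Pi >= 0.62),
    network hub (both high), peripheral otherwise. Requires modules
    assigned by :func:`detect_modules`.
    """
    modules = nx.get_node_attributes(net, "module")
    if len(modules) != net.number_of_nodes():
        raise ParameterError(
            "run detect_modules before computing node roles")
    within = {}
    for node in net.nodes:
        own = modules[node]
        within[node] = sum(1 for nb in net.neighbors(node)
                           if modules[nb] == own)
    by_module: dict = {}
    for node, mid in modules.items():
        by_module.setdefault(mid, []).append(node)
    rows = []
    for node in net.nodes:
        mid = modules[node]
        member_k = np.array([within[nb] for nb in by_module[mid]], float)
        sd = member_k.std(ddof=0)
        zi = 0.0 if sd == 0 else (within[node] - member_k.mean()) / sd
        k_i = net.degree(node)
        per_module: dict = {}
        for nb in net.neighbors(node):
            per_module[modules[nb]] = per_module.get(modules[nb], 0) + 1
        pi = 1.0 - sum((k / k_i) ** 2 for k in per_module.values())
        if zi >= zi_threshold and pi >= pi_threshold:
            role = "network_hub"
        elif zi >= zi_threshold:
            role = "module_hub"
        elif pi >= pi_threshold:
            role = "connector"
        else:
            role = "peripheral"
        rows.append({"otu_id": node, "module": mid, "degree": k_i,
                     "within_module_degree": within[node], "zi": zi,
                     "pi": pi, "role": role})
    return pd.DataFrame(rows).set_index("otu_id")


# ---------------------------------------------------------------------------
# Fraction-level convenience
# ---------------------------------------------------------------------------

def build_fraction_network(table: OtuTable, classes: AbundanceClassMap,
                           fraction: str = "whole",
                           min_prevalence: float = 1 / 3,
                           rho_min: float = DEFAULT_RHO_MIN,
                           p_max: float = DEFAULT_P_MAX) -> nx.Graph:
    """Spearman co-occurrence network for one abundance fraction."""
    sub = table if fraction == "whole" else table.select_otus(
        classes.otus(fraction))
    rho, p, ids = spearman_matrix(sub, min_prevalence=min_prevalence)
    return build_network(rho, p, ids, rho_min=rho_min, p_max=p_max,
                         classes=classes)
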