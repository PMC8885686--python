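"""Synthetic OTU tables, phylogenies, and metadata.

The generator emulates the statistical structure the analysis chain
assumes: two groups of soil samples, a long-tailed (lognormal) OTU
abundance distribution in which a handful of abundant OTUs carry most of
the reads while most OTUs are rare, a phylogeny with a Brownian
(phylogenetically conserved) niche trait, communities drawn either
neutrally from the regional pool or under Gaussian environmental
filtering on that trait, and soil covariates correlated with the
filtering environment.

Assembly modes
--------------
* ``neutral``: every sample is a multinomial draw from the pool.
* ``homogeneous_filtering``: each group shares one environmental
  optimum; sampling weights are
  ``pool_i * exp(-filter_strength * (trait_i - optimum)^2)``. Shared
  selection lowers phylogenetic turnover within groups (betaNTI < -2)
  relative to the regional pool, which spans both groups' clades.
* ``variable_filtering``: each sample draws its own optimum uniformly
  over the trait range, raising turnover (betaNTI > +2).

A single seed fully determines all outputs; per-operation streams are
spawned hierarchically so results do not depend on call order.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .datatypes import OtuTable, SampleMetadata
from .errors import ParameterError

ASSEMBLY_MODES = ("neutral", "homogeneous_filtering", "variable_filtering")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters of the synthetic community generator."""

    n_otus: int = 1500
    n_samples_per_group: int = 15
    depth: int = 20000
    abundance_sigma: float = 3.0
    assembly_mode: str = "neutral"
    filter_strength: float = 15.0
    niche_floor: float = 0.05
    drift_sigma: float = 0.5
    trait_rate: float = 1.0
    trait_conservatism: float = 2.0
    n_nuisance_covariates: int = 3
    nuisance_correlation: float = 0.5
    group_labels: tuple = ("M", "R")
    seed: int = 0

    def __post_init__(self):
        if self.n_otus < 4:
            raise ParameterError("n_otus must be at least 4")
        if self.n_samples_per_group < 2:
            raise ParameterError("need at least 2 samples per group")
        if self.assembly_mode not in ASSEMBLY_MODES:
            raise ParameterError(
                f"assembly_mode must be one of {ASSEMBLY_MODES}")
        if self.filter_strength < 0:
            raise ParameterError("filter_strength must be non-negative")
        if self.abundance_sigma <= 0:
            raise ParameterError("abundance_sigma must be positive")
        if self.drift_sigma < 0:
            raise ParameterError("drift_sigma must be non-negative")
        if not 0 <= self.niche_floor < 1:
            raise ParameterError("niche_floor must be in [0, 1)")
        if self.trait_conservatism < 0:
            raise ParameterError("trait_conservatism must be non-negative")
        if self.depth < 10 * self.n_otus:
            warnings.warn(
                f"depth {self.depth} is below the recommended "
                f"10 x n_otus = {10 * self.n_otus}")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def otu_names(n: int) -> list:
    width = max(4, len(str(n)))
    return [f"OTU{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(n_otus: int, seed=None) -> dendropy.Tree:
    """Random bifurcating tree over ``n_otus`` tips.

    Topology grows by coalescent-style random pairwise joins; every edge
    gets an independent Exponential(1) length, then all lengths are
    rescaled so the mean root-to-tip depth equals 1.
    """
    if n_otus < 2:
        raise ParameterError("a tree needs at least 2 tips")
    rng = _rng(seed)
    labels = otu_names(n_otus)
    tns = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        node.edge.length = float(rng.exponential(1.0))
        nodes.append(node)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.exponential(1.0))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = None
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = True
    # normalize mean tip height to 1
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    scale = float(np.mean(depths))
    for node in tree.preorder_node_iter():
        if node.edge.length is not None:
            node.edge.length /= scale
    return tree


# ---------------------------------------------------------------------------
# Trait
# ---------------------------------------------------------------------------

def simulate_trait(tree: dendropy.Tree, rate: float = 1.0, seed=None,
                   conservatism: float = 0.0) -> pd.Series:
    """Brownian-motion niche trait along the tree from a root value of 0.

    With ``conservatism=0`` this is plain Brownian motion: tip covariance
    equals the shared root-to-MRCA path length times ``rate``, so closely
    related OTUs get similar niches. Positive ``conservatism`` damps the
    Brownian step variance by ``exp(-2 * conservatism * depth)`` (an
    early-burst model): trait divergence then happens mostly along deep
    branches, mimicking the deep phylogenetic conservation of bacterial
    habitat preferences, so that niche-based filtering selects
    near-monophyletic groups rather than convergent taxa from across the
    tree.
    """
    if rate < 0:
        raise ParameterError("Brownian rate must be non-negative")
    if conservatism < 0:
        raise ParameterError("conservatism must be non-negative")
    rng = _rng(seed)
    values = {tree.seed_node: 0.0}
    depth = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length or 0.0
        parent = node.parent_node
        depth[node] = depth[parent] + length
        sd = np.sqrt(rate * length) * np.exp(-conservatism * depth[parent])
        step = rng.normal(0.0, sd) if rate > 0 and sd > 0 else 0.0
        values[node] = values[parent] + step
    tips = {leaf.taxon.label: values[leaf]
            for leaf in tree.leaf_node_iter()}
    return pd.Series(tips, name="trait")


# ---------------------------------------------------------------------------
# Regional pool
# ---------------------------------------------------------------------------

def simulate_pool_abundances(n_otus: int, abundance_sigma: float,
                             seed=None) -> np.ndarray:
    """Lognormal relative abundances summing to 1, indexed by OTU.

    Draws are i.i.d., so the abundance rank of an OTU is independent of
    its position in the phylogeny; sorting the result gives the usual
    monotone rank-abundance curve.
    """
    if abundance_sigma <= 0:
        raise ParameterError("abundance_sigma must be positive")
    rng = _rng(seed)
    raw = rng.lognormal(0.0, abundance_sigma, size=n_otus)
    return raw / raw.sum()


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def simulate_communities(cfg: SimulationConfig, tree: dendropy.Tree,
                         traits: pd.Series, pool: np.ndarray,
                         seed=None):
    """Draw the sample-by-OTU count table plus matching metadata.

    Returns ``(OtuTable, SampleMetadata)``. Every sample sums exactly to
    ``cfg.depth``. The ``env`` covariate records each sample's filtering
    optimum (pure noise in neutral mode); nuisance covariates correlate
    with ``env`` at ``cfg.nuisance_correlation``.
    """
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != cfg.n_otus or len(pool) != cfg.n_otus:
        raise ParameterError("tree/pool dimensions do not match the config")
    trait = traits.reindex(labels).to_numpy()
    if np.isnan(trait).any():
        raise ParameterError("traits do not cover all tree tips")
    rng = _rng(seed if seed is not None else cfg.seed)
    n_samples = 2 * cfg.n_samples_per_group
    sample_ids = [f"{g}{i + 1:02d}" for g in cfg.group_labels
                  for i in range(cfg.n_samples_per_group)]
    groups = [g for g in cfg.group_labels
              for _ in range(cfg.n_samples_per_group)]

    lo, hi = float(trait.min()), float(trait.max())
    if cfg.assembly_mode == "neutral":
        optima = np.full(n_samples, np.nan)
        env = rng.normal(0.0, 1.0, size=n_samples)
    elif cfg.assembly_mode == "homogeneous_filtering":
        # one shared optimum per group: each group is a single homogeneous
        # environment, so selection is homogeneous within groups while the
        # regional pool still spans both groups' selected clades
        per_group = rng.uniform(lo, hi, size=len(cfg.group_labels))
        optima = np.repeat(per_group, cfg.n_samples_per_group)
        env = optima.copy()
    else:  # variable_filtering
        optima = rng.uniform(lo, hi, size=n_samples)
        env = optima.copy()

    counts = np.empty((n_samples, cfg.n_otus), dtype=np.int64)
    for s in range(n_samples):
        if cfg.assembly_mode == "neutral" or cfg.filter_strength == 0:
            weights = pool.astype(float)
        else:
            kernel = np.exp(-cfg.filter_strength
                            * (trait - optima[s]) ** 2)
            # hard niche boundary: taxa whose suitability falls below the
            # floor are truly absent from the sample, not merely scarce
            kernel[kernel < cfg.niche_floor] = 0.0
            weights = pool * kernel
            total = weights.sum()
            if not np.isfinite(total) or total <= 0:
                raise ParameterError(
                    "environmental filter annihilated every OTU; lower "
                    "filter_strength or niche_floor")
            weights = weights / total
        if cfg.drift_sigma > 0:
            # demographic drift / micro-heterogeneity: per-sample lognormal
            # overdispersion so replicate communities differ
            # compositionally, as replicate soils do; the noise is
            # phylogeny-independent, so it leaves null-model calibration
            # intact
            weights = weights * np.exp(
                cfg.drift_sigma * rng.normal(size=cfg.n_otus))
        counts[s] = rng.multinomial(cfg.depth, weights / weights.sum())

    env_sd = env.std()
    env_z = (env - env.mean()) / env_sd if env_sd > 0 else np.zeros_like(env)
    r = cfg.nuisance_correlation
    cov = {"env": env}
    for k in range(cfg.n_nuisance_covariates):
        noise = rng.normal(0.0, 1.0, size=n_samples)
        cov[f"cov{k + 1}"] = r * env_z + np.sqrt(1 - r ** 2) * noise
    meta = pd.DataFrame({"group": groups, **cov},
                        index=pd.Index(sample_ids, name="sample_id"))
    return (OtuTable(tuple(sample_ids), tuple(labels), counts),
            SampleMetadata(meta))


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedDataset:
    config: SimulationConfig
    table: OtuTable
    metadata: SampleMetadata
    tree: dendropy.Tree = field(repr=False)
    traits: pd.Series = field(repr=False)
    pool: np.ndarray = field(repr=False)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Deterministically generate the full dataset for a config.

    The top-level seed is split into four independent streams (tree,
    trait, pool, communities), so the same seed reproduces every output
    regardless of which operations are called individually.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_tree, s_trait, s_pool, s_comm = ss.spawn(4)
    tree = simulate_tree(cfg.n_otus, seed=s_tree)
    traits = simulate_trait(tree, rate=cfg.trait_rate, seed=s_trait,
                            conservatism=cfg.trait_conservatism)
    pool = simulate_pool_abundances(cfg.n_otus, cfg.abundance_sigma,
                                    seed=s_pool)
    table, metadata = simulate_communities(cfg, tree, traits, pool,
                                           seed=s_comm)
    return SimulatedDataset(config=cfg, table=table, metadata=metadata,
                            tree=tree, traits=traits, pool=pool)


def with_mode(cfg: SimulationConfig, mode: str,
              **overrides) -> SimulationConfig:
    """Convenience: copy a config with a different assembly mode."""
    return replace(cfg, assembly_mode=mode, **overrides)
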