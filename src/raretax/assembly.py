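"""Phylogenetic null-model inference of community assembly.

Within-sample clustering is measured by the mean nearest taxon distance
(MNTD) and its standardized effect size, the nearest taxon index (NTI).
Between samples, phylogenetic turnover is the beta mean nearest taxon
distance (betaMNTD); its standardized deviation from a tip-shuffle null,
betaNTI, separates deterministic from stochastic assembly:

* betaNTI < -2 : less turnover than expected -> homogeneous selection
* betaNTI > +2 : more turnover than expected -> variable selection
* |betaNTI| < 2: stochastic assembly (drift, dispersal)

The null model shuffles taxon labels across the tips of the phylogeny
("taxa labels" randomization): community composition and abundances stay
fixed while phylogenetic relationships among the occurring taxa are
randomized. The shuffle pool is exactly the OTU set of the analyzed
table, so each abundance fraction is evaluated against its own pool.
"""
from __future__ import annotations

import itertools
import logging
import warnings

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import AbundanceClassMap, OtuTable
from .errors import ComputationError, ConsistencyError, ParameterError

log = logging.getLogger(__name__)

BNTI_CUTOFF = 2.0


# ---------------------------------------------------------------------------
# Cophenetic distances
# ---------------------------------------------------------------------------

def cophenetic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Tip-to-tip path-length matrix of a tree with branch lengths.

    Computed in O(n^2) by combining root-to-tip depths with the depth of
    each pair's most recent common ancestor:
    ``d(i, j) = depth(i) + depth(j) - 2 * depth(mrca(i, j))``.
    """
    leaves = list(tree.leaf_node_iter())
    ids = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise ComputationError("tree has an unlabeled tip")
        ids.append(leaf.taxon.label)
    if len(set(ids)) != len(ids):
        raise ComputationError("tree has duplicated tip labels")
    index = {leaf: i for i, leaf in enumerate(leaves)}
    n = len(leaves)

    depth: dict = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None:
            raise ComputationError(
                "missing branch length; load the tree in lenient mode "
                "to treat missing lengths as 0")
        depth[node] = depth[node.parent_node] + float(length)

    tip_depth = np.array([depth[leaf] for leaf in leaves])
    d = np.zeros((n, n))
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = np.array([index[node]], dtype=np.intp)
            continue
        child_sets = [below.pop(c) for c in node.child_nodes()]
        for a, b in itertools.combinations(child_sets, 2):
            block = (tip_depth[a][:, None] + tip_depth[b][None, :]
                     - 2.0 * depth[node])
            d[np.ix_(a, b)] = block
            d[np.ix_(b, a)] = block.T
        below[node] = np.concatenate(child_sets)
    return DistanceMatrix(d, ids=ids)


def _aligned_distance(table: OtuTable, coph: DistanceMatrix) -> np.ndarray:
    tree_ids = set(coph.ids)
    missing = [o for o in table.otu_ids if o not in tree_ids]
    if missing:
        raise ConsistencyError(
            f"OTUs absent from the phylogeny: {missing[:5]}")
    extra = tree_ids - set(table.otu_ids)
    if extra:
        log.warning("ignoring %d phylogeny tips absent from the table",
                    len(extra))
    return coph.filter(list(table.otu_ids)).data


def _weights(table: OtuTable, weighted: bool) -> np.ndarray:
    counts = table.counts.astype(float)
    if weighted:
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            return np.where(totals > 0, counts / totals, 0.0)
    present = counts > 0
    richness = present.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        return np.where(present, 1.0 / np.maximum(richness, 1), 0.0)


# ---------------------------------------------------------------------------
# betaMNTD (single pair, reference form)
# ---------------------------------------------------------------------------

def beta_mntd(x_counts, y_counts, d: np.ndarray,
              weighted: bool = True) -> float:
    """Between-community mean nearest taxon distance for one sample pair.

    ``0.5 * [sum_i w_i min_j d(i,j) + sum_j w_j min_i d(j,i)]`` with the
    sums over taxa present in one community and minima over taxa present
    in the other; weights are relative abundances (``weighted=True``) or
    ``1/richness``.
    """
    x = np.asarray(x_counts, float)
    y = np.asarray(y_counts, float)
    ix = np.flatnonzero(x > 0)
    iy = np.flatnonzero(y > 0)
    if len(ix) == 0 or len(iy) == 0:
        raise ComputationError("betaMNTD undefined for an empty sample")
    if weighted:
        wx = x[ix] / x[ix].sum()
        wy = y[iy] / y[iy].sum()
    else:
        wx = np.full(len(ix), 1.0 / len(ix))
        wy = np.full(len(iy), 1.0 / len(iy))
    sub = d[np.ix_(ix, iy)]
    return 0.5 * float(wx @ sub.min(axis=1) + wy @ sub.min(axis=0))


# ---------------------------------------------------------------------------
# betaNTI over all requested pairs
# ---------------------------------------------------------------------------

def _pair_betamntd(d: np.ndarray, idx: list, w: np.ndarray,
                   pairs: list, perm: np.ndarray | None) -> np.ndarray:
    """betaMNTD for every pair under an optional tip-label permutation.

    For each sample ``s`` the vector ``m_s[i] = min_{j in s} d'(i, j)``
    (``d'`` = permuted distances) is computed once; a pair's betaMNTD is
    then two weighted dot products. This makes the 999-draw null loop
    linear in samples rather than pairs.
    """
    n_otus = d.shape[0]
    dp = d if perm is None else d[perm]
    m = np.empty((len(idx), n_otus))
    for s, ids in enumerate(idx):
        cols = ids if perm is None else perm[ids]
        m[s] = dp[:, cols].min(axis=1)
    out = np.empty(len(pairs))
    for k, (a, b) in enumerate(pairs):
        out[k] = 0.5 * (w[a] @ m[b] + w[b] @ m[a])
    return out


def beta_nti(table: OtuTable, coph: DistanceMatrix, weighted: bool = True,
             n_null: int = 999, seed=None,
             sample_pairs: list | None = None) -> pd.DataFrame:
    """betaNTI for sample pairs of ``table`` against a tip-shuffle null.

    Returns one row per pair with the observed betaMNTD, the null mean
    and standard deviation over ``n_null`` tip-label shuffles, the
    standardized betaNTI, the deterministic/stochastic call at
    ``|betaNTI| > 2``, and a ``degenerate`` flag for null distributions
    with zero spread (betaNTI reported as 0).
    """
    if n_null < 2:
        raise ParameterError("n_null must be at least 2")
    d = _aligned_distance(table, coph)
    totals = table.sample_sums()
    if (totals == 0).any():
        raise ComputationError("betaNTI undefined with empty samples")
    idx = [np.flatnonzero(row > 0) for row in table.counts]
    w = _weights(table, weighted)
    n_samples = table.n_samples
    if sample_pairs is None:
        pairs = list(itertools.combinations(range(n_samples), 2))
    else:
        pos = {s: i for i, s in enumerate(table.sample_ids)}
        pairs = [(pos[a], pos[b]) for a, b in sample_pairs]
    obs = _pair_betamntd(d, idx, w, pairs, None)

    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, len(pairs)))
    n_otus = d.shape[0]
    for t in range(n_null):
        perm = rng.permutation(n_otus)
        nulls[t] = _pair_betamntd(d, idx, w, pairs, perm)
    null_mean = nulls.mean(axis=0)
    null_sd = nulls.std(axis=0, ddof=1)
    degenerate = null_sd <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        bnti = np.where(degenerate, 0.0, (obs - null_mean) / null_sd)
    return pd.DataFrame({
        "sample_a": [table.sample_ids[a] for a, _ in pairs],
        "sample_b": [table.sample_ids[b] for _, b in pairs],
        "beta_mntd_obs": obs,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "beta_nti": bnti,
        "call": np.where(np.abs(bnti) > BNTI_CUTOFF, "deterministic",
                         "stochastic"),
        "degenerate": degenerate,
    })


# ---------------------------------------------------------------------------
# MNTD / NTI (within samples)
# ---------------------------------------------------------------------------

def _sample_mntd(d: np.ndarray, ids: np.ndarray, w_row: np.ndarray,
                 perm: np.ndarray | None) -> float:
    rows = ids if perm is None else perm[ids]
    sub = d[np.ix_(rows, rows)].copy()
    np.fill_diagonal(sub, np.inf)
    nearest = sub.min(axis=1)
    return float(w_row[ids] @ nearest)


def mntd_nti(table: OtuTable, coph: DistanceMatrix, weighted: bool = True,
             n_null: int = 999, seed=None) -> pd.DataFrame:
    """Per-sample MNTD and NTI against the tip-shuffle null.

    ``NTI = -(MNTD_obs - mean(MNTD_null)) / sd(MNTD_null)``; positive
    values indicate phylogenetic clustering. Samples with fewer than two
    taxa are reported with missing values.
    """
    if n_null < 2:
        raise ParameterError("n_null must be at least 2")
    d = _aligned_distance(table, coph)
    idx = [np.flatnonzero(row > 0) for row in table.counts]
    w = _weights(table, weighted)
    # weights must sum to 1 over present taxa for a weighted mean
    rng = np.random.default_rng(seed)
    perms = [rng.permutation(d.shape[0]) for _ in range(n_null)]
    rows = []
    for s, ids in enumerate(idx):
        if len(ids) < 2:
            warnings.warn(
                f"sample {table.sample_ids[s]!r} has <2 taxa; NTI undefined")
            rows.append({"sample_id": table.sample_ids[s],
                         "mntd": np.nan, "null_mean": np.nan,
                         "null_sd": np.nan, "nti": np.nan,
                         "degenerate": True})
            continue
        obs = _sample_mntd(d, ids, w[s], None)
        null = np.array([_sample_mntd(d, ids, w[s], p) for p in perms])
        sd = null.std(ddof=1)
        degenerate = sd <= 1e-12
        nti = 0.0 if degenerate else -(obs - null.mean()) / sd
        rows.append({"sample_id": table.sample_ids[s], "mntd": obs,
                     "null_mean": null.mean(), "null_sd": sd,
                     "nti": nti, "degenerate": degenerate})
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Summaries and fraction-level wrappers
# ---------------------------------------------------------------------------

def summarize_assembly(bnti: pd.DataFrame,
                       groups: pd.Series | None = None) -> pd.DataFrame:
    """Median betaNTI and process fractions, overall or per group.

    When ``groups`` is given, only within-group pairs contribute and one
    row is emitted per group. Degenerate pairs are excluded.
    """
    df = bnti[~bnti["degenerate"]]
    if groups is not None:
        groups = groups.astype(str)
        ga = df["sample_a"].map(groups)
        gb = df["sample_b"].map(groups)
        df = df[ga == gb].assign(group=ga[ga == gb])
    else:
        df = df.assign(group="all")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        b = sub["beta_nti"]
        rows.append({
            "group": g,
            "n_pairs": len(sub),
            "median_beta_nti": b.median(),
            "frac_deterministic": (b.abs() > BNTI_CUTOFF).mean(),
            "frac_homogeneous_selection": (b < -BNTI_CUTOFF).mean(),
            "frac_variable_selection": (b > BNTI_CUTOFF).mean(),
        })
    return pd.DataFrame(rows).set_index("group")


def within_group_pairs(table: OtuTable, groups: pd.Series) -> list:
    """All unordered sample pairs that share a group label."""
    groups = groups.astype(str)
    pairs = []
    for a, b in itertools.combinations(table.sample_ids, 2):
        if groups[a] == groups[b]:
            pairs.append((a, b))
    return pairs


def beta_nti_by_fraction(table: OtuTable, coph: DistanceMatrix,
                         classes: AbundanceClassMap, weighted: bool = True,
                         n_null: int = 999, seed=None,
                         sample_pairs: list | None = None) -> pd.DataFrame:
    """betaNTI separately for the whole, abundant, and rare fractions.

    Each fraction uses its own OTU pool (and hence its own shuffle null).
    Samples with no reads in a fraction are dropped for that fraction
    with a warning.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    out = []
    for fraction, child in zip(("whole", "abundant", "rare"), ss.spawn(3)):
        sub = table if fraction == "whole" else table.select_otus(
            classes.otus(fraction))
        keep = sub.sample_sums() > 0
        if not keep.all():
            skipped = [s for s, k in zip(sub.sample_ids, keep) if not k]
            warnings.warn(
                f"samples without {fraction} reads skipped: {skipped}")
            sub = sub.select_samples(
                [s for s, k in zip(sub.sample_ids, keep) if k])
        pairs = sample_pairs
        if pairs is not None:
            kept = set(sub.sample_ids)
            pairs = [(a, b) for a, b in pairs if a in kept and b in kept]
        res = beta_nti(sub, coph, weighted=weighted, n_null=n_null,
                       seed=child, sample_pairs=pairs)
        res.insert(0, "fraction", fraction)
        out.append(res)
    return pd.concat(out, ignore_index=True)
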