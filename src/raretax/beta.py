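"""Between-sample statistics: Bray-Curtis, NMDS, rank tests with FDR,
Mantel tests, and redundancy analysis with forward selection.

Distance matrices are carried as :class:`skbio.DistanceMatrix` so sample
ids travel with the numbers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.manifold import smacof
from statsmodels.stats.multitest import multipletests

from .datatypes import OtuTable
from .errors import ComputationError, ParameterError

# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` between samples."""
    if (table.sample_sums() == 0).any():
        raise ComputationError("Bray-Curtis undefined for empty samples")
    d = pdist(table.counts.astype(float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(table.sample_ids))


def hellinger(table: OtuTable) -> np.ndarray:
    """Hellinger transform: square root of relative abundances."""
    return np.sqrt(table.relative_abundance())


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------


@dataclass
class NmdsResult:
    coordinates: pd.DataFrame
    stress: float  # Kruskal stress-1


def _classical_mds(d2: np.ndarray, k: int) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d2 ** 2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(dm: DistanceMatrix, k: int = 2, n_starts: int = 50, seed=None,
         max_iter: int = 300, eps: float = 1e-6) -> NmdsResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Runs SMACOF with monotone regression from a classical-MDS start plus
    ``n_starts`` random starts, keeping the lowest-stress solution. The
    classical start makes the result equivariant under relabeling of the
    input ids when ``n_starts=0``.
    """
    d = dm.data
    n = d.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be below the sample count {n}")
    if n_starts < 0:
        raise ParameterError("n_starts must be >= 0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pos, stress = smacof(d, metric=False, n_components=k,
                             init=_classical_mds(d, k), n_init=1,
                             max_iter=max_iter, eps=eps,
                             normalized_stress=True)
        if n_starts > 0:
            rng = np.random.default_rng(seed)
            pos_r, stress_r = smacof(
                d, metric=False, n_components=k, n_init=n_starts,
                max_iter=max_iter, eps=eps, normalized_stress=True,
                random_state=int(rng.integers(2 ** 31)))
            if stress_r < stress:
                pos, stress = pos_r, stress_r
    coords = pd.DataFrame(pos, index=pd.Index(list(dm.ids), name="sample_id"),
                          columns=[f"NMDS{i + 1}" for i in range(k)])
    return NmdsResult(coordinates=coords, stress=float(stress))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum with BH-FDR
# ---------------------------------------------------------------------------


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if pooled.std() == 0:
        # all observations identical: no evidence either way
        return 0.0, 1.0
    if max(len(x), len(y)) <= 10 and not ties:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
    else:
        res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided",
                                       method="asymptotic",
                                       use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_fdr(values_by_group: dict, pairs: list) -> pd.DataFrame:
    """Two-sided rank-sum tests for the listed group pairs with BH-FDR.

    Exact p-values are used for groups of up to 10 tie-free observations,
    a tie-corrected normal approximation otherwise. ``q`` is the
    Benjamini-Hochberg adjusted p across the tested family.
    """
    rows = []
    for a, b in pairs:
        stat, p = _ranksum_p(values_by_group[a], values_by_group[b])
        rows.append({"group_a": a, "group_b": b, "statistic": stat, "p": p})
    df = pd.DataFrame(rows)
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------


def mantel(d1: DistanceMatrix, d2: DistanceMatrix, method: str = "spearman",
           n_perm: int = 999, seed=None) -> tuple:
    """One-sided (positive association) Mantel test.

    ``r`` correlates the lower-triangle entries of the two matrices;
    significance comes from jointly permuting rows and columns of ``d2``,
    with the add-one permutation p-value
    ``(1 + #[r_perm >= r_obs]) / (1 + n_perm)``.
    """
    if list(d1.ids) != list(d2.ids):
        d2 = d2.filter(d1.ids)
    m1, m2 = d1.data, d2.data
    n = m1.shape[0]
    iu = np.triu_indices(n, 1)
    x = m1[iu]
    y = m2[iu]
    if x.std() == 0 or y.std() == 0:
        raise ComputationError("Mantel r undefined for a constant matrix")
    if method == "spearman":
        x = scipy.stats.rankdata(x)
    elif method != "pearson":
        raise ParameterError(f"unknown method {method!r}")
    xc = x - x.mean()
    xn = np.sqrt((xc ** 2).sum())

    def corr_rows(rows: np.ndarray) -> np.ndarray:
        if method == "spearman":
            rows = scipy.stats.rankdata(rows, axis=1)
        rc = rows - rows.mean(axis=1, keepdims=True)
        denom = np.sqrt((rc ** 2).sum(axis=1)) * xn
        return (rc @ xc) / denom

    r_obs = float(corr_rows(y[None, :])[0])
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    y_perm = m2[perms[:, iu[0]], perms[:, iu[1]]]
    r_perm = corr_rows(y_perm)
    p = (1 + int((r_perm >= r_obs - 1e-12).sum())) / (1 + n_perm)
    return r_obs, p


# ---------------------------------------------------------------------------
# RDA with forward selection
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    selected: list
    axis_variance_fractions: np.ndarray
    site_scores: pd.DataFrame
    constrained_fraction: float
    pvalues: dict = field(default_factory=dict)
    dropped_collinear: list = field(default_factory=list)


def _zscore_covariates(cov: pd.DataFrame):
    keep, dropped = [], []
    for c in cov.columns:
        if cov[c].std(ddof=0) == 0:
            dropped.append(c)
        else:
            keep.append(c)
    if dropped:
        warnings.warn(f"dropping constant covariate(s): {dropped}")
    z = (cov[keep] - cov[keep].mean()) / cov[keep].std(ddof=0)
    return z, dropped


def _drop_collinear(z: pd.DataFrame):
    cols, dropped = [], []
    x = np.empty((len(z), 0))
    for c in z.columns:
        cand = np.column_stack([x, z[c].to_numpy()])
        if np.linalg.matrix_rank(cand, tol=1e-10) > x.shape[1]:
            x = cand
            cols.append(c)
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"dropping collinear covariate(s): {dropped}")
    return z[cols], dropped


def _basis(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-12
    return q[:, keep]


def rda_forward(table, covariates: pd.DataFrame, n_perm: int = 199,
                seed=None, alpha: float = 0.05, k: int = 2,
                transform: str = "hellinger") -> RdaResult:
    """Redundancy analysis with permutation-based forward selection.

    The community matrix (Hellinger-transformed by default) is regressed
    on standardized covariates; RDA axes are the principal components of
    the fitted values, with variance fractions relative to the total
    community variance. Forward selection adds, at each step, the
    covariate with the largest gain in constrained variance, testing the
    best candidate's pseudo-F against Freedman-Lane permutations of the
    current-model residuals (the null statistic is the maximum over
    remaining candidates, so the test is selection-aware); selection
    stops when p > alpha.
    """
    if isinstance(table, OtuTable):
        y = hellinger(table) if transform == "hellinger" \
            else table.relative_abundance() if transform == "relative" \
            else table.counts.astype(float)
        sample_ids = list(table.sample_ids)
    else:
        y = np.asarray(table, float)
        sample_ids = list(covariates.index)
    covariates = covariates.loc[sample_ids] if set(sample_ids).issubset(
        covariates.index) else covariates
    n = y.shape[0]
    yc = y - y.mean(axis=0)
    total_ss = float((yc ** 2).sum())
    if total_ss == 0:
        raise ComputationError("community matrix has zero variance")
    z, dropped_const = _zscore_covariates(covariates)
    z, dropped_coll = _drop_collinear(z)
    dropped = dropped_const + dropped_coll

    rng = np.random.default_rng(seed)
    selected: list = []
    pvalues: dict = {}
    remaining = list(z.columns)
    while remaining:
        x_sel = z[selected].to_numpy() if selected else np.empty((n, 0))
        q_sel = _basis(x_sel) if selected else np.empty((n, 0))
        fit0 = q_sel @ (q_sel.T @ yc) if selected else np.zeros_like(yc)
        resid0 = yc - fit0
        res0_ss = float((resid0 ** 2).sum())
        # unit residual direction of each candidate given selected set
        qc = []
        for c in remaining:
            v = z[c].to_numpy().astype(float)
            v = v - q_sel @ (q_sel.T @ v) if selected else v - v.mean()
            nv = np.linalg.norm(v)
            qc.append(v / nv if nv > 1e-10 else np.zeros(n))
        qc = np.array(qc)  # (n_cand, n)
        df_res = n - len(selected) - 2

        def max_f(res: np.ndarray) -> tuple:
            gains = ((qc @ res) ** 2).sum(axis=1)
            rss = float((res ** 2).sum())
            f = gains / np.maximum((rss - gains) / max(df_res, 1), 1e-300)
            i = int(np.argmax(f))
            return f[i], i

        f_obs, best = max_f(resid0)
        count = 0
        for _ in range(n_perm):
            res_p = resid0[rng.permutation(n)]
            f_p, _ = max_f(res_p)
            if f_p >= f_obs - 1e-12:
                count += 1
        p = (1 + count) / (1 + n_perm)
        pvalues[remaining[best]] = p
        if p <= alpha:
            selected.append(remaining.pop(best))
        else:
            break

    if selected:
        q_sel = _basis(z[selected].to_numpy())
        y_fit = q_sel @ (q_sel.T @ yc)
        u, s, vt = np.linalg.svd(y_fit, full_matrices=False)
        n_axes = min(len(selected), y.shape[1], n - 1)
        fractions = (s[:n_axes] ** 2) / total_ss
        scores = u[:, :n_axes] * s[:n_axes]
        constrained = float((y_fit ** 2).sum() / total_ss)
    else:
        n_axes = 0
        fractions = np.array([])
        scores = np.empty((n, 0))
        constrained = 0.0
    score_df = pd.DataFrame(scores, index=pd.Index(sample_ids,
                                                   name="sample_id"),
                            columns=[f"RDA{i + 1}" for i in range(n_axes)])
    return RdaResult(selected=selected, axis_variance_fractions=fractions,
                     site_scores=score_df, constrained_fraction=constrained,
                     pvalues=pvalues, dropped_collinear=dropped)
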