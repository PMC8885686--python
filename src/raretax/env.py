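"""Community-environment association tables.

For every (fraction, group, covariate) cell a Mantel test correlates the
Bray-Curtis community distance with the Euclidean distance of the
z-scored covariate; significance stars are assigned from BH-adjusted
p-values across the whole table.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .beta import bh_adjust, bray_curtis, mantel
from .datatypes import AbundanceClassMap, OtuTable, SampleMetadata
from .diversity import FRACTIONS


def significance_stars(q: float) -> str:
    if q < 0.001:
        return "***"
    if q < 0.01:
        return "**"
    if q < 0.05:
        return "*"
    return ""


def _covariate_distance(values: np.ndarray, ids) -> DistanceMatrix:
    z = (values - values.mean()) / values.std(ddof=0)
    return DistanceMatrix(np.abs(z[:, None] - z[None, :]), ids=list(ids))


def mantel_screen(table: OtuTable, classes: AbundanceClassMap,
                  metadata: SampleMetadata, n_perm: int = 999,
                  seed=None, method: str = "spearman") -> pd.DataFrame:
    """Mantel r/p for each fraction x group x covariate combination.

    Constant covariates within a group are skipped with a flag (NaN r).
    Returns a long-format frame with columns fraction, group, covariate,
    r, p, q, stars.
    """
    metadata = metadata.aligned_to(table)
    groups = metadata.group
    covariates = metadata.covariates
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows = []
    for fraction in FRACTIONS:
        sub_f = table if fraction == "whole" else table.select_otus(
            classes.otus(fraction))
        for group in sorted(groups.unique()):
            sample_ids = [s for s in table.sample_ids
                          if groups[s] == group]
            sub = sub_f.select_samples(sample_ids)
            keep = sub.sample_sums() > 0 if sub.n_otus else \
                np.zeros(sub.n_samples, bool)
            if not keep.all():
                skipped = [s for s, k in zip(sub.sample_ids, keep) if not k]
                warnings.warn(
                    f"samples without {fraction} reads skipped: {skipped}")
                sub = sub.select_samples(
                    [s for s, k in zip(sub.sample_ids, keep) if k])
            if sub.n_samples < 3:
                warnings.warn(
                    f"too few samples for Mantel in fraction {fraction!r}, "
                    f"group {group!r}; cells reported as missing")
                for cov in covariates.columns:
                    rows.append({"fraction": fraction, "group": group,
                                 "covariate": cov, "r": np.nan,
                                 "p": np.nan, "skipped_constant": False})
                continue
            bc = bray_curtis(sub)
            for cov in covariates.columns:
                values = covariates.loc[list(sub.sample_ids), cov]
                values = values.to_numpy(float)
                if values.std(ddof=0) == 0:
                    rows.append({"fraction": fraction, "group": group,
                                 "covariate": cov, "r": np.nan,
                                 "p": np.nan, "skipped_constant": True})
                    continue
                dcov = _covariate_distance(values, sub.sample_ids)
                r, p = mantel(bc, dcov, method=method, n_perm=n_perm,
                              seed=ss.spawn(1)[0])
                rows.append({"fraction": fraction, "group": group,
                             "covariate": cov, "r": r, "p": p,
                             "skipped_constant": False})
    df = pd.DataFrame(rows)
    tested = ~df["p"].isna()
    q = np.full(len(df), np.nan)
    q[tested.to_numpy()] = bh_adjust(df.loc[tested, "p"].to_numpy())
    df["q"] = q
    df["stars"] = ["" if np.isnan(v) else significance_stars(v) for v in q]
    return df


def mantel_table(screen: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long screen into covariates x (group, fraction) cells."""
    wide = screen.pivot_table(index="covariate",
                              columns=["group", "fraction"],
                              values="r", sort=False)
    return wide
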