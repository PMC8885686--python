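"""OTU-table filtering, rarefaction, and alpha-diversity estimation.

Index conventions
-----------------
* Shannon ``H`` uses the natural logarithm.
* Simpson is reported as the concentration :math:`\\sum p_i^2` (small
  values mean high diversity), consistent with values of order 1e-3
  reported for species-rich soil communities.
* Chao1 uses the bias-corrected form
  :math:`S + F_1 (F_1 - 1) / (2 (F_2 + 1))`, which stays finite when no
  doubletons are observed.
* Pielou's evenness ``J = H / ln(S)`` (0 for a single-OTU sample).
* Good's coverage ``1 - F1 / N``.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import AbundanceClassMap, OtuTable
from .errors import ComputationError, ParameterError

FRACTIONS = ("whole", "abundant", "rare")


def filter_low_count_otus(table: OtuTable, min_total: int = 2) -> OtuTable:
    """Drop OTUs whose total count across samples is below ``min_total``.

    With the default of 2 this removes global singletons and all-zero
    OTUs. Samples are never dropped; a sample left with zero reads
    triggers a warning and is retained for the caller to decide.
    """
    keep = table.otu_sums() >= min_total
    out = OtuTable(table.sample_ids,
                   tuple(o for o, k in zip(table.otu_ids, keep) if k),
                   table.counts[:, keep])
    empty = [s for s, t in zip(out.sample_ids, out.sample_sums()) if t == 0]
    if empty:
        warnings.warn(f"samples with zero reads after OTU filtering: {empty}")
    return out


def rarefy(table: OtuTable, depth: int, seed=None) -> OtuTable:
    """Subsample every sample to ``depth`` reads without replacement."""
    if depth <= 0:
        raise ParameterError("rarefaction depth must be positive")
    totals = table.sample_sums()
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ParameterError(
            f"sample(s) below rarefaction depth {depth}: {short}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i, row in enumerate(table.counts):
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(table.sample_ids, table.otu_ids, out)


def _alpha_one(counts: np.ndarray) -> dict:
    counts = counts[counts > 0]
    n_reads = counts.sum()
    if n_reads == 0:
        raise ComputationError("empty sample has no diversity")
    s_obs = len(counts)
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    p = counts / n_reads
    shannon = float(-(p * np.log(p)).sum())
    return {
        "observed_richness": s_obs,
        "chao1": s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)),
        "shannon": shannon,
        "simpson": float((p ** 2).sum()),
        "pielou": shannon / np.log(s_obs) if s_obs > 1 else 0.0,
        "goods_coverage": 1.0 - f1 / n_reads,
    }


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Alpha-diversity indices per sample (rows follow sample order)."""
    records = [_alpha_one(row) for row in table.counts]
    return pd.DataFrame(records,
                        index=pd.Index(list(table.sample_ids),
                                       name="sample_id"))


def alpha_diversity_by_fraction(table: OtuTable,
                                classes: AbundanceClassMap) -> pd.DataFrame:
    """Long-format alpha diversity for the whole/abundant/rare fractions.

    Each fraction is the sub-table restricted to that class's OTUs with
    original counts retained; indices are computed on within-sub-table
    proportions. Samples with no reads in a fraction are skipped with a
    warning.
    """
    out = []
    for fraction in FRACTIONS:
        sub = table if fraction == "whole" else table.select_otus(
            classes.otus(fraction))
        nonzero = sub.sample_sums() > 0
        if not nonzero.all():
            skipped = [s for s, k in zip(sub.sample_ids, nonzero) if not k]
            warnings.warn(
                f"samples without {fraction} reads skipped: {skipped}")
            sub = sub.select_samples(
                [s for s, k in zip(sub.sample_ids, nonzero) if k])
        rec = alpha_diversity(sub).reset_index()
        rec.insert(1, "fraction", fraction)
        out.append(rec)
    return pd.concat(out, ignore_index=True)
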