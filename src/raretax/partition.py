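"""Abundance-class partitioning of OTUs.

An OTU is *abundant* when its mean relative abundance across samples is at
least 0.1% (0.001), *rare* when the mean is below 0.01% (0.0001), and
*moderate* otherwise. Per-sample "locally abundant" flags (>0.1% within a
single sample) are emitted for reporting but never change the class: the
final three-way partition rests on the regional (mean-across-samples)
criterion only.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import AbundanceClassMap, OtuTable
from .errors import ConsistencyError, ParameterError

DEFAULT_ABUNDANT_THRESH = 0.001   # mean relative abundance >= 0.1%
DEFAULT_RARE_THRESH = 0.0001      # mean relative abundance  < 0.01%
DEFAULT_LOCAL_THRESH = 0.001      # within-sample 0.1% cut for local flags


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Per-sample relative abundances; each row sums to 1."""
    return table.relative_abundance()


def classify_taxa(table: OtuTable,
                  abundant_thresh: float = DEFAULT_ABUNDANT_THRESH,
                  rare_thresh: float = DEFAULT_RARE_THRESH,
                  local_thresh: float = DEFAULT_LOCAL_THRESH,
                  ) -> AbundanceClassMap:
    """Three-way abundant / moderate / rare partition of the OTU set.

    The mean relative abundance is the arithmetic mean over all samples,
    zeros included, which makes the classification invariant to sample
    and OTU ordering.
    """
    if not (0.0 < rare_thresh < abundant_thresh < 1.0):
        raise ParameterError(
            f"thresholds must satisfy 0 < rare ({rare_thresh}) < "
            f"abundant ({abundant_thresh}) < 1")
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=0)
    label = np.where(mean_rel >= abundant_thresh, "abundant",
                     np.where(mean_rel < rare_thresh, "rare", "moderate"))
    frame = pd.DataFrame(
        {"label": label, "mean_rel_abund": mean_rel},
        index=pd.Index(list(table.otu_ids), name="otu_id"))
    local = pd.DataFrame(rel > local_thresh,
                         index=list(table.sample_ids),
                         columns=list(table.otu_ids))
    return AbundanceClassMap(frame=frame, local_abundant=local)


def partition_summary(table: OtuTable,
                      classes: AbundanceClassMap) -> pd.DataFrame:
    """Per class: fraction of OTUs and mean per-sample fraction of reads."""
    if set(classes.frame.index) != set(table.otu_ids):
        raise ConsistencyError("class map OTUs do not match the table")
    labels = classes.frame["label"].reindex(list(table.otu_ids)).to_numpy()
    rel = relative_abundance(table)
    rows = []
    for lab in ("abundant", "moderate", "rare"):
        mask = labels == lab
        rows.append({
            "label": lab,
            "n_otus": int(mask.sum()),
            "otu_fraction": mask.mean(),
            "mean_read_fraction": rel[:, mask].sum(axis=1).mean()
            if mask.any() else 0.0,
        })
    return pd.DataFrame(rows).set_index("label")
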