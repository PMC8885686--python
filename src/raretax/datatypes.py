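"""Shared in-memory containers for the analysis chain.

The canonical orientation for community data is samples as rows and OTUs
as columns, matching the way field ecologists lay out site-by-species
matrices. All identifiers are case-sensitive strings.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OtuTable:
    """Integer count matrix of shape (samples, OTUs) with identifiers.

    Parameters
    ----------
    sample_ids : sequence of str
        Row identifiers, unique.
    otu_ids : sequence of str
        Column identifiers, unique.
    counts : ndarray of int
        Non-negative read counts, shape ``(len(sample_ids), len(otu_ids))``.
    """

    sample_ids: tuple
    otu_ids: tuple
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix (samples x OTUs)")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)):
                raise FormatError("counts contain non-finite values")
            if not np.all(counts == np.floor(counts)):
                raise FormatError("counts must be integers")
        counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise FormatError("counts must be non-negative")
        sample_ids = tuple(str(s) for s in self.sample_ids)
        otu_ids = tuple(str(o) for o in self.otu_ids)
        if counts.shape != (len(sample_ids), len(otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(otu_ids)} OTUs"
            )
        _check_unique(sample_ids, "sample")
        _check_unique(otu_ids, "OTU")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "otu_ids", otu_ids)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def otu_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    # -- conversions ----------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)),
                   df.to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids),
                            columns=list(self.otu_ids))

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts; raises if any sample is empty."""
        from .errors import ComputationError

        totals = self.sample_sums()
        if (totals == 0).any():
            bad = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ComputationError(f"sample(s) with zero total reads: {bad}")
        return self.counts / totals[:, None]

    # -- subsetting ------------------------------------------------------
    def select_otus(self, otu_ids) -> "OtuTable":
        otu_ids = [str(o) for o in otu_ids]
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        missing = [o for o in otu_ids if o not in pos]
        if missing:
            raise ConsistencyError(f"OTUs not in table: {missing[:5]}")
        idx = [pos[o] for o in otu_ids]
        return OtuTable(self.sample_ids, tuple(otu_ids), self.counts[:, idx])

    def select_samples(self, sample_ids) -> "OtuTable":
        sample_ids = [str(s) for s in sample_ids]
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise ConsistencyError(f"samples not in table: {missing[:5]}")
        idx = [pos[s] for s in sample_ids]
        return OtuTable(tuple(sample_ids), self.otu_ids, self.counts[idx, :])


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample group label plus numeric soil covariates.

    ``frame`` is indexed by sample id, holds one categorical ``group``
    column (e.g. M = monoculture, R = rotation) and any number of numeric
    covariate columns (pH, TOC, TN, ...). Missing covariate values are
    rejected at construction.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        df = self.frame
        if "group" not in df.columns:
            raise FormatError("metadata must contain a 'group' column")
        _check_unique(list(df.index), "sample")
        cov = df.drop(columns="group")
        try:
            cov = cov.astype(float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric covariate value: {exc}") from exc
        if cov.isna().any().any():
            bad = cov.columns[cov.isna().any()].tolist()
            raise FormatError(f"missing covariate values in columns: {bad}")
        out = pd.concat([df[["group"]].astype(str), cov], axis=1)
        out.index = out.index.map(str)
        object.__setattr__(self, "frame", out)

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.frame.index)

    @property
    def group(self) -> pd.Series:
        return self.frame["group"]

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame.drop(columns="group")

    def aligned_to(self, table: OtuTable) -> "SampleMetadata":
        """Reorder to the table's sample order; ids must match exactly."""
        if set(self.sample_ids) != set(table.sample_ids):
            raise ConsistencyError(
                "metadata sample ids do not match the OTU table")
        return SampleMetadata(self.frame.loc[list(table.sample_ids)])


LABELS = ("abundant", "moderate", "rare")


@dataclass(frozen=True)
class AbundanceClassMap:
    """Per-OTU abundance class with the mean relative abundance it rests on.

    ``frame`` is indexed by OTU id with columns ``label`` (one of
    ``abundant``/``moderate``/``rare``) and ``mean_rel_abund``. The
    per-sample local flags (>0.1% within a sample) are kept for reporting
    only and never alter the class.
    """

    frame: pd.DataFrame
    local_abundant: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        df = self.frame
        if not {"label", "mean_rel_abund"}.issubset(df.columns):
            raise FormatError(
                "class map needs 'label' and 'mean_rel_abund' columns")
        bad = set(df["label"]) - set(LABELS)
        if bad:
            raise FormatError(f"unknown class labels: {sorted(bad)}")
        _check_unique(list(df.index), "OTU")

    def otus(self, fraction: str) -> list:
        """OTU ids belonging to ``fraction`` ('whole' returns all)."""
        if fraction == "whole":
            return list(self.frame.index)
        if fraction not in LABELS:
            raise ValueError(f"unknown fraction {fraction!r}")
        return list(self.frame.index[self.frame["label"] == fraction])
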