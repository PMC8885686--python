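"""Readers and writers for the external representations.

Formats
-------
* OTU table: TSV (samples as rows, first column = sample id, header row =
  OTU ids) or BIOM-JSON (v1, dense or sparse matrix, observations = OTUs).
* Sample metadata: TSV with a ``group`` column plus numeric covariates.
* Phylogeny: Newick with branch lengths (tips = OTU ids).
* Co-occurrence network: GraphML or a flat edge list TSV
  (source, target, rho, p_adj, sign).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import AbundanceClassMap, OtuTable, SampleMetadata
from .errors import FormatError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# OTU tables
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv") -> OtuTable:
    """Load and validate an OTU count table.

    ``format`` is ``"tsv"`` (samples x OTUs, tab separated) or
    ``"biom-json"`` (BIOM v1 JSON, dense or sparse). Duplicated ids,
    negative or non-integer counts, and empty samples are format errors.
    """
    path = Path(path)
    if format == "tsv":
        table = _read_otu_tsv(path)
    elif format == "biom-json":
        table = _read_biom_json(path)
    else:
        raise ValueError(f"unknown OTU table format {format!r}")
    if (table.sample_sums() == 0).any():
        bad = [s for s, t in zip(table.sample_ids, table.sample_sums())
               if t == 0]
        raise FormatError(f"sample(s) with zero total reads: {bad}")
    return table


def _read_otu_tsv(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    otu_ids = header[1:]
    if len(set(otu_ids)) != len(otu_ids):
        dup = sorted({o for o in otu_ids if otu_ids.count(o) > 1})
        raise FormatError(f"duplicated OTU column(s): {dup[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=None,
                     names=["_sample"] + otu_ids, skiprows=1, dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count in {path}: {exc}") from exc
    if not np.all(np.isfinite(values)) or np.any(values != np.floor(values)):
        raise FormatError(f"non-integer count in {path}")
    return OtuTable(tuple(df.index), tuple(otu_ids), values.astype(np.int64))


def _read_biom_json(path: Path) -> OtuTable:
    with open(path, encoding="utf-8") as fh:
        obj = json.load(fh)
    try:
        otu_ids = [r["id"] for r in obj["rows"]]
        sample_ids = [c["id"] for c in obj["columns"]]
        mtype = obj.get("matrix_type", "dense")
        data = obj["data"]
    except (KeyError, TypeError) as exc:
        raise FormatError(f"not a BIOM-JSON table: missing {exc}") from exc
    mat = np.zeros((len(otu_ids), len(sample_ids)))
    if mtype == "dense":
        arr = np.asarray(data, dtype=float)
        if arr.shape != mat.shape:
            raise FormatError("BIOM dense data shape mismatch")
        mat = arr
    elif mtype == "sparse":
        for r, c, v in data:
            mat[int(r), int(c)] = v
    else:
        raise FormatError(f"unsupported BIOM matrix_type {mtype!r}")
    if np.any(mat != np.floor(mat)):
        raise FormatError("non-integer count in BIOM table")
    # BIOM stores observations (OTUs) as rows; transpose to samples x OTUs.
    return OtuTable(tuple(sample_ids), tuple(otu_ids),
                    mat.T.astype(np.int64))


def write_otu_table(table: OtuTable, path) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    out = meta.frame.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Class maps
# ---------------------------------------------------------------------------

def read_classes(path) -> AbundanceClassMap:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return AbundanceClassMap(df)


def write_classes(classes: AbundanceClassMap, path) -> None:
    out = classes.frame.copy()
    out.index.name = "otu_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_tree(path, strict: bool = True) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths.

    In strict mode a missing branch length (other than on the root edge)
    is a format error; with ``strict=False`` it is replaced by 0.
    Duplicate or missing tip labels and negative lengths always raise.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    return validate_tree(tree, strict=strict)


def validate_tree(tree: dendropy.Tree, strict: bool = True) -> dendropy.Tree:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise FormatError("tree has an unlabeled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise FormatError(f"duplicated tip label(s): {dup[:5]}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            if strict:
                raise FormatError(
                    "missing branch length (use strict=False to treat as 0)")
            node.edge.length = 0.0
        elif node.edge.length < 0:
            raise FormatError(f"negative branch length {node.edge.length}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def tip_labels(tree: dendropy.Tree) -> list:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def prune_tree_to(tree: dendropy.Tree, otu_ids) -> dendropy.Tree:
    """Return a copy pruned to ``otu_ids``; extra tips are dropped with a
    logged warning. Requested ids missing from the tree raise."""
    from .errors import ConsistencyError

    keep = set(map(str, otu_ids))
    present = set(tip_labels(tree))
    missing = keep - present
    if missing:
        raise ConsistencyError(
            f"OTUs absent from the tree: {sorted(missing)[:5]}")
    extra = present - keep
    pruned = tree.clone(depth=1)
    if extra:
        log.warning("pruning %d tree tips absent from the OTU table",
                    len(extra))
        pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

_EDGE_COLS = ["source", "target", "rho", "p_adj", "sign"]


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Persist a co-occurrence network with its edge attributes."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        rows = [
            {"source": u, "target": v, "rho": d.get("rho", np.nan),
             "p_adj": d.get("p_adj", np.nan), "sign": d.get("sign", 0)}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t",
                                                      index=False)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        raw = nx.read_graphml(path)
        net = nx.Graph()
        for n, d in raw.nodes(data=True):
            net.add_node(str(n), **d)
        for u, v, d in raw.edges(data=True):
            attrs = dict(d)
            for key in ("rho", "p_adj"):
                if key in attrs:
                    attrs[key] = float(attrs[key])
            if "sign" in attrs:
                attrs["sign"] = int(attrs["sign"])
            net.add_edge(str(u), str(v), **attrs)
        return net
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        net = nx.Graph()
        for _, row in df.iterrows():
            net.add_edge(str(row["source"]), str(row["target"]),
                         rho=float(row["rho"]), p_adj=float(row["p_adj"]),
                         sign=int(row["sign"]))
        return net
    raise ValueError(f"unknown network format {format!r}")
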