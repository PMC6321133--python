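"""Data model and file I/O for tables, trees, references and networks.

This module owns every format convention in the package:

* all feature tables are TSV, UTF-8, samples as rows, features as columns,
  "." decimal;
* a missing metabolite measurement ("not detected") is an empty cell on disk
  and NaN in memory — it is *not* zero, and the distinction drives the
  detection filter;
* phylogenies are Newick (the only dialect supported), read through
  scikit-bio; a missing branch length is replaced by 0 with a warning;
* correlation networks are exported as GraphML plus a flat edge-list TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "SampleMetadata",
    "FeatureTable",
    "PhyloTree",
    "GeneContentReference",
    "PathwayLibrary",
    "CorrelationNetwork",
    "read_feature_table",
    "write_feature_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_gene_content",
    "write_gene_content",
    "read_pathway_library",
    "write_pathway_library",
    "write_network",
    "read_network",
]

BLOCKS = ("metabolite", "taxon", "gene-set")


class FormatError(ValueError):
    """Raised when an on-disk file violates the package's format contract."""


@dataclass
class SampleMetadata:
    """Per-sample design information.

    ``df`` is indexed by unique sample id with columns ``group`` (two levels,
    e.g. control/AD), ``subject_id`` and ``age_weeks``.
    """

    df: pd.DataFrame

    def __post_init__(self):
        required = {"group", "subject_id", "age_weeks"}
        missing = required - set(self.df.columns)
        if missing:
            raise FormatError(f"metadata missing columns: {sorted(missing)}")
        if self.df.index.duplicated().any():
            raise FormatError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def groups(self) -> pd.Series:
        return self.df["group"]

    def group_levels(self) -> list[str]:
        return sorted(self.df["group"].unique())


@dataclass
class FeatureTable:
    """A samples x features numeric matrix with a block label and unit.

    ``data`` is indexed by sample id; NaN encodes "not detected" (distinct
    from a true zero).  ``block`` is one of metabolite / taxon / gene-set,
    ``unit`` one of count / concentration / fraction / scaled.
    """

    data: pd.DataFrame
    block: str
    unit: str = "count"

    def __post_init__(self):
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if self.data.index.duplicated().any():
            raise FormatError("duplicate sample ids")
        vals = self.data.to_numpy(dtype=float)
        if self.unit in ("count", "concentration", "fraction"):
            if np.nanmin(vals, initial=0.0) < 0:
                raise FormatError(f"negative values invalid for unit {self.unit!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.block, self.unit)

    def align_to(self, meta: SampleMetadata) -> "FeatureTable":
        """Reorder rows to match the metadata's sample order."""
        missing = set(meta.sample_ids) - set(self.data.index)
        if missing:
            raise FormatError(f"samples missing from table: {sorted(missing)}")
        return FeatureTable(self.data.loc[meta.sample_ids], self.block, self.unit)


@dataclass
class PhyloTree:
    """A rooted phylogeny with branch lengths, leaves labelled by taxon id."""

    tree: TreeNode

    @property
    def leaf_ids(self) -> list[str]:
        return [t.name for t in self.tree.tips()]

    @property
    def total_branch_length(self) -> float:
        return float(sum(n.length or 0.0 for n in self.tree.traverse()
                         if not n.is_root()))


@dataclass
class GeneContentReference:
    """Reference gene content used for metagenome prediction.

    ``copy_number``: 16S rRNA gene copies per taxon (>= 1).
    ``ko_content``: taxa x KO gene-family count matrix.
    ``pathway_map``: KO -> set of pathway ids; KOs absent from the map are
    kept but flagged in ``unmapped_kos``.
    """

    copy_number: pd.Series
    ko_content: pd.DataFrame
    pathway_map: dict[str, set[str]]
    unmapped_kos: set[str] = field(default_factory=set)

    def __post_init__(self):
        if (self.copy_number < 1).any():
            raise FormatError("16S copy numbers must be >= 1")
        self.unmapped_kos = {k for k in self.ko_content.columns
                             if k not in self.pathway_map}

    @property
    def taxa(self) -> list[str]:
        return list(self.ko_content.index)

    def pathways(self) -> list[str]:
        out: set[str] = set()
        for ps in self.pathway_map.values():
            out |= ps
        return sorted(out)


@dataclass
class PathwayLibrary:
    """Metabolite-set library for over-representation analysis.

    ``universe_size`` is the number of metabolites in the library universe
    (the N of the hypergeometric test); ``pathways`` maps pathway name to its
    member metabolite set (the "Total" column of an enrichment report).
    """

    universe_size: int
    pathways: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self):
        largest = max((len(m) for m in self.pathways.values()), default=0)
        if self.universe_size < largest:
            raise FormatError("universe size smaller than largest pathway")
        if self.universe is not None:
            for name, members in self.pathways.items():
                stray = members - self.universe
                if stray:
                    raise FormatError(
                        f"pathway {name!r} has members outside the universe: "
                        f"{sorted(stray)[:5]}")


@dataclass
class CorrelationNetwork:
    """Cross-block Spearman correlation network.

    ``graph`` holds all selected features as nodes (attributes: block,
    cluster, direction) with edges only for pairs significant at the FDR
    threshold (attributes: rho, q, sign).  ``pairs`` records every tested
    pair with its rho, p and q.
    """

    graph: nx.Graph
    pairs: pd.DataFrame

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


# ---------------------------------------------------------------------------
# feature tables and metadata


def read_feature_table(path, block: str, unit: str = "count") -> FeatureTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if pd.Index(header).duplicated().any():
        raise FormatError(f"duplicate feature columns in {path}")
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return FeatureTable(df.astype(float), block=block, unit=unit)


def write_feature_table(tbl: FeatureTable, path) -> None:
    # empty cell on disk <=> NaN in memory ("not detected")
    tbl.data.to_csv(path, sep="\t", na_rep="", index_label="sample_id",
                    encoding="utf-8")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    df.index = df.index.astype(str)
    df.index.name = None
    df["age_weeks"] = df["age_weeks"].astype(int)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", index_label="sample_id", encoding="utf-8")


# ---------------------------------------------------------------------------
# trees


def read_newick(path) -> PhyloTree:
    try:
        tree = TreeNode.read(str(path), format="newick", convert_underscores=False)
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}") from exc
    n_missing = 0
    for node in tree.traverse():
        if node.is_root():
            continue
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif not np.isfinite(node.length) or node.length < 0:
            raise FormatError("branch lengths must be finite and non-negative")
    if n_missing:
        warnings.warn(f"{n_missing} branch length(s) missing; defaulted to 0",
                      RuntimeWarning, stacklevel=2)
    return PhyloTree(tree)


def write_newick(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# gene content reference (a directory of three TSVs)


def read_gene_content(directory) -> GeneContentReference:
    d = Path(directory)
    cn = pd.read_csv(d / "copy_number.tsv", sep="\t", index_col=0)["copy_number"]
    cn.index = cn.index.astype(str)
    cn.index.name = None
    ko = pd.read_csv(d / "ko_content.tsv", sep="\t", index_col=0)
    ko.index = ko.index.astype(str)
    ko.index.name = None
    pm_long = pd.read_csv(d / "pathway_map.tsv", sep="\t")
    pathway_map: dict[str, set[str]] = {}
    for ko_id, pw in zip(pm_long["ko"].astype(str), pm_long["pathway"].astype(str)):
        pathway_map.setdefault(ko_id, set()).add(pw)
    return GeneContentReference(cn.astype(int), ko.astype(float), pathway_map)


def write_gene_content(ref: GeneContentReference, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    ref.copy_number.rename("copy_number").to_csv(d / "copy_number.tsv", sep="\t",
                                                 index_label="taxon")
    ref.ko_content.to_csv(d / "ko_content.tsv", sep="\t", index_label="taxon")
    rows = [(ko, pw) for ko, pws in sorted(ref.pathway_map.items())
            for pw in sorted(pws)]
    pd.DataFrame(rows, columns=["ko", "pathway"]).to_csv(
        d / "pathway_map.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# pathway library (long TSV: pathway <tab> metabolite; '#universe_size=N' header)


def read_pathway_library(path) -> PathwayLibrary:
    n = None
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#universe_size="):
            n = int(first.strip().split("=", 1)[1])
            long = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            long = pd.read_csv(fh, sep="\t")
    pathways: dict[str, set[str]] = {}
    for pw, met in zip(long["pathway"].astype(str), long["metabolite"].astype(str)):
        pathways.setdefault(pw, set()).add(met)
    members = set().union(*pathways.values()) if pathways else set()
    if n is None:
        n = len(members)
    return PathwayLibrary(universe_size=n, pathways=pathways)


def write_pathway_library(lib: PathwayLibrary, path) -> None:
    rows = [(pw, m) for pw, ms in sorted(lib.pathways.items()) for m in sorted(ms)]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#universe_size={lib.universe_size}\n")
        pd.DataFrame(rows, columns=["pathway", "metabolite"]).to_csv(
            fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# correlation networks


def write_network(net: CorrelationNetwork, path_prefix) -> tuple[Path, Path]:
    """Write GraphML plus a flat edge-list TSV.

    ``path_prefix`` may be a directory-plus-stem; ``<prefix>.graphml`` and
    ``<prefix>_edges.tsv`` are produced.  The TSV replaces interactive
    network rendering: columns source, target, rho, q, sign.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    gml = prefix.with_suffix(".graphml")
    g = nx.Graph()
    for node, attrs in net.graph.nodes(data=True):
        g.add_node(node, **{k: ("" if v is None else v) for k, v in attrs.items()})
    for u, v, attrs in net.graph.edges(data=True):
        g.add_edge(u, v, **attrs)
    nx.write_graphml(g, gml)
    edges = prefix.parent / (prefix.name + "_edges.tsv")
    rows = [(u, v, a.get("rho"), a.get("q"), a.get("sign"))
            for u, v, a in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["source", "target", "rho", "q", "sign"]).to_csv(
        edges, sep="\t", index=False)
    return gml, edges


def read_network(graphml_path) -> CorrelationNetwork:
    g = nx.read_graphml(graphml_path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    rows = [(u, v, a.get("rho"), np.nan, a.get("q"))
            for u, v, a in g.edges(data=True)]
    pairs = pd.DataFrame(rows, columns=["feature_a", "feature_b", "rho", "p", "q"])
    return CorrelationNetwork(graph=g, pairs=pairs)
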