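"""Integration stage: the metabologenomic layer.

Combines the per-block analyses into cross-omics views: Procrustes
superimposition of the metabolome PCA onto the microbiome PCoA (goodness of
fit M^2 over the first three dimensions), per-block feature-feature Spearman
autocorrelation maps cut into a fixed number of clusters by Euclidean
hierarchical clustering (7 metabolite, 5 genus and 3 gene-set clusters by
default), selection of features that differ between diet groups
(Mann-Whitney + BH, q < 0.05), and a cross-block Spearman correlation
network over the selected features with edges at BH FDR < 0.05.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist
from scipy.stats import rankdata
from scipy.stats import t as _t_dist

from .stats import bh_fdr, differential_table
from .tables_io import CorrelationNetwork, FeatureTable, SampleMetadata

__all__ = [
    "ProcrustesResult",
    "procrustes",
    "autocorrelation_map",
    "hca_clusters",
    "select_differential",
    "build_network",
]

DEFAULT_CLUSTER_K = {"metabolite": 7, "taxon": 5, "gene-set": 3}


@dataclass
class ProcrustesResult:
    """Least-squares superimposition of one ordination onto another.

    ``m2`` is the sum of squared deviations between the two standardised
    configurations after optimal translation, uniform scaling and rotation,
    over the first min(k, 3) dimensions.  ``reference`` and ``transformed``
    hold the superimposed coordinates per sample.
    """

    m2: float
    reference: pd.DataFrame
    transformed: pd.DataFrame


def procrustes(coords_a: pd.DataFrame, coords_b: pd.DataFrame,
               k: int = 3) -> ProcrustesResult:
    """Superimpose configuration ``b`` onto reference ``a``.

    Both inputs are samples x dimensions frames over the same samples in the
    same order (by convention ``a`` is the metabolome PCA, ``b`` the
    microbiome PCoA).  Only the first min(k, available) dimensions enter the
    fit; M^2 = 0 iff the configurations are identical up to a similarity
    transform.
    """
    if list(coords_a.index) != list(coords_b.index):
        raise ValueError("sample sets/order differ between configurations")
    kk = min(k, coords_a.shape[1], coords_b.shape[1])
    if kk < 2:
        raise ValueError("need at least 2 shared dimensions")
    a = coords_a.to_numpy(dtype=float)[:, :kk]
    b = coords_b.to_numpy(dtype=float)[:, :kk]
    mtx1, mtx2, disparity = _scipy_procrustes(a, b)
    cols = list(coords_a.columns[:kk])
    return ProcrustesResult(
        m2=float(disparity),
        reference=pd.DataFrame(mtx1, index=coords_a.index, columns=cols),
        transformed=pd.DataFrame(mtx2, index=coords_a.index, columns=cols),
    )


def _rank_columns(data: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(rankdata, 0, data.to_numpy(dtype=float))


def autocorrelation_map(tbl: FeatureTable) -> pd.DataFrame:
    """Feature x feature Spearman correlation matrix of one block.

    Symmetric with unit diagonal; constant features yield NaN rows/columns
    (flagged with a warning).  Equivalent to calling
    :func:`~metabologenomics.stats.spearman_rho` on every pair, but computed
    as a Pearson correlation of midranks for speed.
    """
    data = tbl.data.fillna(0)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 samples for a correlation map")
    ranks = _rank_columns(data)
    sd = ranks.std(axis=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant feature(s): correlation "
                      "undefined (NaN)", RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks, rowvar=False)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    return pd.DataFrame(rho, index=data.columns, columns=data.columns)


def hca_clusters(matrix: pd.DataFrame, k: int,
                 method: str = "complete") -> pd.Series:
    """Cut a Euclidean hierarchical clustering of the matrix rows into
    exactly ``k`` clusters.

    The rows are typically the rows of an autocorrelation map (so features
    cluster by their correlation profile); passing a samples-major abundance
    table transposed clusters raw profiles instead.  Labels are integers
    1..k, renumbered in order of first appearance so the assignment is
    deterministic given the input row order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = matrix.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of features ({n})")
    vals = matrix.to_numpy(dtype=float)
    vals = np.nan_to_num(vals, nan=0.0)
    if k == n:
        labels = np.arange(n)
    else:
        z = linkage(pdist(vals, metric="euclidean"), method=method)
        labels = cut_tree(z, n_clusters=k).ravel()
    # renumber by first appearance
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[i] = remap[lab]
    return pd.Series(out, index=matrix.index, name="cluster")


def select_differential(tbl: FeatureTable, meta: SampleMetadata,
                        q_thresh: float = 0.05,
                        levels: tuple[str, str] = ("control", "AD"),
                        per_subject_mean: bool = False,
                        ) -> tuple[FeatureTable, pd.DataFrame]:
    """Features whose abundance differs between the two diet groups.

    Mann-Whitney U + BH within the block; keeps q < ``q_thresh``.  Returns
    the restricted table and the full differential report (U, p, q, group
    means, fold change = mean(case)/mean(reference), NaN when the reference
    mean is zero — rendered "-" in text reports).  ``per_subject_mean``
    averages repeated measurements per animal before testing instead of
    pooling timepoints as independent observations.
    """
    report = differential_table(
        tbl.data, meta.groups, levels=levels,
        subjects=meta.df["subject_id"] if per_subject_mean else None)
    selected = report.index[report["q"] < q_thresh].tolist()
    sub = FeatureTable(tbl.data.loc[:, selected], tbl.block, tbl.unit)
    return sub, report


def build_network(blocks: dict[str, FeatureTable], q_thresh: float = 0.05,
                  within_block: bool = False,
                  clusters: dict[str, pd.Series] | None = None,
                  directions: dict[str, str] | None = None,
                  ) -> CorrelationNetwork:
    """Cross-block Spearman correlation network at BH FDR < ``q_thresh``.

    ``blocks`` maps block label -> feature table of the *selected*
    (differential) features; all tables must share the same samples in the
    same order.  Every cross-block feature pair (plus within-block pairs if
    requested) receives a Spearman rho and a t-approximation p-value; BH is
    applied jointly over all computed pairs; edges are kept at q <
    ``q_thresh`` and signed by rho.  Node attributes: block, cluster (from
    ``clusters``, per block) and direction (from ``directions``, per
    feature, e.g. the group a feature is elevated in).
    """
    if len(blocks) < 2 and not within_block:
        raise ValueError("need at least two blocks for a cross-block network")
    items = list(blocks.items())
    index = items[0][1].data.index
    for name, tbl in items:
        if not tbl.data.index.equals(index):
            raise ValueError(f"block {name!r} has mismatched samples")
    if len(index) == 0:
        raise ValueError("no shared samples")

    ranked = {name: _rank_columns(tbl.data.fillna(0)) for name, tbl in blocks.items()}
    n = len(index)

    pair_rows: list[tuple[str, str, float]] = []
    combos = list(itertools.combinations(blocks, 2))
    if within_block:
        combos += [(b, b) for b in blocks]
    for ba, bb in combos:
        ra, rb = ranked[ba], ranked[bb]
        feats_a = blocks[ba].feature_ids
        feats_b = blocks[bb].feature_ids
        za = _standardise(ra)
        zb = _standardise(rb)
        rho = za.T @ zb / n
        for i, fa in enumerate(feats_a):
            j_start = i + 1 if ba == bb else 0
            for j in range(j_start, len(feats_b)):
                pair_rows.append((fa, feats_b[j], float(rho[i, j])))

    pairs = pd.DataFrame(pair_rows, columns=["feature_a", "feature_b", "rho"])
    pairs["p"] = _spearman_p(pairs["rho"].to_numpy(), n)
    pairs["q"] = bh_fdr(pairs["p"].to_numpy())

    graph = nx.Graph()
    for name, tbl in blocks.items():
        cl = clusters.get(name) if clusters else None
        for feat in tbl.feature_ids:
            graph.add_node(
                feat, block=name,
                cluster=int(cl.loc[feat]) if cl is not None and feat in cl.index else None,
                direction=directions.get(feat) if directions else None)
    sig = pairs[pairs["q"] < q_thresh]
    for _, row in sig.iterrows():
        graph.add_edge(row["feature_a"], row["feature_b"], rho=float(row["rho"]),
                       q=float(row["q"]), sign="+" if row["rho"] >= 0 else "-")
    return CorrelationNetwork(graph=graph, pairs=pairs)


def _standardise(ranks: np.ndarray) -> np.ndarray:
    mu = ranks.mean(axis=0)
    sd = ranks.std(axis=0)
    sd = np.where(sd == 0, np.nan, sd)
    return (ranks - mu) / sd


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Spearman rho via the t approximation (df = n-2)."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * _t_dist.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return np.where(np.isnan(rho), np.nan, np.minimum(p, 1.0))
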