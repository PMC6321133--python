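"""Microbiome stage: everything downstream of a genus/OTU count table.

Rarefaction to a common read depth, relative abundances, alpha diversity
(observed taxa, Chao1, Shannon), unweighted and weighted UniFrac distances,
principal coordinate analysis, ANOSIM, a LEfSe-style LDA effect-size screen
and PICRUSt-style metagenome prediction (16S copy-number normalisation
followed by multiplication with a reference gene-content matrix and
aggregation of KO families into pathways).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from scipy.stats import kruskal, rankdata
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .metabolome import OrdinationResult
from .tables_io import FeatureTable, GeneContentReference, PhyloTree

__all__ = [
    "AnosimResult",
    "LdaEffect",
    "PredictedMetagenome",
    "rarefy",
    "relative_abundance",
    "top_taxa",
    "alpha_diversity",
    "unifrac",
    "pcoa",
    "anosim",
    "lda_effect_size",
    "predict_metagenome",
]

log = logging.getLogger(__name__)

RAREFACTION_DEPTH = 16_014  # filter-passed reads subsampled per sample


@dataclass
class AnosimResult:
    R: float
    p: float
    n_perm: int


@dataclass
class LdaEffect:
    feature: str
    lda_score: float
    direction: str  # group with the higher mean abundance


@dataclass
class PredictedMetagenome:
    """Predicted KO-family and pathway abundance tables (samples x features)."""

    ko_table: FeatureTable
    pathway_table: FeatureTable


# ---------------------------------------------------------------------------
# rarefaction and relative abundance


def rarefy(counts: FeatureTable, depth: int = RAREFACTION_DEPTH,
           seed: int | None = None) -> FeatureTable:
    """Subsample each sample's reads to a common depth without replacement.

    Samples with fewer than ``depth`` reads are dropped with a warning.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    data = counts.data.fillna(0).astype(np.int64)
    totals = data.sum(axis=1)
    shallow = totals[totals < depth].index.tolist()
    if shallow:
        log.warning("dropping %d sample(s) below depth %d: %s",
                    len(shallow), depth, shallow)
        data = data.drop(index=shallow)
    rng = np.random.default_rng(seed)
    out = np.empty(data.shape, dtype=np.int64)
    for i, (_, row) in enumerate(data.iterrows()):
        out[i] = rng.multivariate_hypergeometric(row.to_numpy(), depth)
    return FeatureTable(pd.DataFrame(out, index=data.index, columns=data.columns),
                        block=counts.block, unit="count")


def relative_abundance(counts: FeatureTable) -> FeatureTable:
    """Row-normalise counts to fractions summing to 1."""
    data = counts.data.fillna(0).astype(float)
    totals = data.sum(axis=1)
    if (totals <= 0).any():
        bad = totals[totals <= 0].index.tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    return FeatureTable(data.div(totals, axis=0), block=counts.block,
                        unit="fraction")


def top_taxa(relab: FeatureTable, min_mean: float = 0.01) -> list[str]:
    """Taxa whose average relative abundance across all samples exceeds
    ``min_mean`` (default 1%), most abundant first."""
    means = relab.data.mean(axis=0)
    return means[means > min_mean].sort_values(ascending=False).index.tolist()


# ---------------------------------------------------------------------------
# alpha diversity


def alpha_diversity(counts: FeatureTable) -> pd.DataFrame:
    """Observed taxa, bias-corrected Chao1 and Shannon entropy per sample.

    Chao1 = S + F1(F1-1)/(2(F2+1)) with F1/F2 the singleton/doubleton counts;
    it requires integer (post-rarefaction) counts.  Shannon uses natural log.
    """
    data = counts.data.fillna(0)
    arr = data.to_numpy(dtype=float)
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("alpha diversity (Chao1) requires integer counts")
    arr = np.round(arr).astype(np.int64)
    observed = (arr > 0).sum(axis=1)
    f1 = (arr == 1).sum(axis=1)
    f2 = (arr == 2).sum(axis=1)
    chao1 = observed + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    totals = arr.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = arr / totals
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame({"observed": observed, "chao1": chao1,
                         "shannon": shannon}, index=data.index)


# ---------------------------------------------------------------------------
# beta diversity


def unifrac(counts: FeatureTable, tree: PhyloTree, weighted: bool = False,
            normalized: bool = False) -> DistanceMatrix:
    """Unweighted or weighted UniFrac distances between all sample pairs.

    Unweighted UniFrac is the fraction of covered branch length unique to
    one of the two communities; weighted UniFrac is
    ``sum_b l_b |A_b/A_T - B_b/B_T|``, optionally normalised by
    ``sum_b l_b (A_b/A_T + B_b/B_T)``.  Weighted defaults to the raw
    (non-normalised) form.  Computed via scikit-bio; the test suite checks
    agreement with an exhaustive branch-walk oracle on small trees.
    """
    taxa = counts.feature_ids
    leaves = set(tree.leaf_ids)
    missing = sorted(set(taxa) - leaves)
    if missing:
        raise ValueError(f"taxa absent from the tree: {missing}")
    data = counts.data.fillna(0).to_numpy(dtype=float)
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    kwargs = {"normalized": normalized} if weighted else {}
    return beta_diversity(metric, data, ids=counts.sample_ids, taxa=taxa,
                          tree=tree.tree, validate=True, **kwargs)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinate analysis (Gower double-centering + eigh).

    Negative eigenvalues (arising from non-Euclidean distances such as raw
    weighted UniFrac) are reported in ``eigvals`` rather than silently
    dropped or zeroed; coordinates are returned for the positive axes only.
    Axis signs follow the same largest-|score| convention as PCA.  Explained
    variance uses the sum of positive eigenvalues as denominator.
    """
    d = np.asarray(dm.data, dtype=float)
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d ** 2) @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(abs(eigvals).max(initial=0.0), 1.0) * n * np.finfo(float).eps
    n_pos = int((eigvals > tol).sum())
    kk = n_pos if k is None else min(k, n_pos)
    scores = eigvecs[:, :kk] * np.sqrt(eigvals[:kk])
    for j in range(scores.shape[1]):
        i = int(np.argmax(np.abs(scores[:, j])))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    pos_sum = eigvals[:n_pos].sum()
    comps = [f"PCo{i+1}" for i in range(kk)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=list(dm.ids), columns=comps),
        loadings=None,
        explained_variance_ratio=pd.Series(
            eigvals[:kk] / pos_sum if pos_sum > 0 else np.zeros(kk),
            index=comps),
        eigvals=pd.Series(eigvals),
    )


def anosim(dm: DistanceMatrix, groups: pd.Series, n_perm: int = 999,
           seed: int | None = None) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 distance pairs; the permutation p-value carries the +1
    correction.  Implemented here for seedable permutations and
    cross-checked against scikit-bio's implementation in the tests.
    """
    labels = np.asarray(groups.loc[list(dm.ids)])
    if pd.unique(labels).size < 2:
        raise ValueError("ANOSIM requires at least two groups")
    condensed = squareform(np.asarray(dm.data), checks=False)
    ranks = rankdata(condensed)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    m = condensed.size
    denom = m / 2.0

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return float((ranks[~within].mean() - ranks[within].mean()) / denom)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R=r_obs, p=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect size

LEFSE_SCALE = 1_000_000.0  # relative abundances rescaled as in LEfSe


def lda_effect_size(relab: FeatureTable, groups: pd.Series, n_boot: int = 30,
                    threshold: float = 2.0, alpha: float = 0.05,
                    seed: int | None = 0) -> list[LdaEffect]:
    """Two-class LDA effect-size screen for differentially abundant taxa.

    Follows the published two-class LEfSe recipe without the subclass step:
    a Kruskal-Wallis screen at ``alpha`` (equivalent to Mann-Whitney for two
    groups), then a bootstrapped linear discriminant analysis on the
    surviving features (abundances rescaled to sum 1e6 as in LEfSe).  The
    per-feature effect size averages the LDA-axis displacement and the raw
    class-mean difference; the reported score is log10(1 + |effect|), signed
    implicitly by the ``direction`` attribute.  Only features with
    |score| > ``threshold`` are returned.
    """
    levels = sorted(pd.unique(groups.loc[relab.sample_ids]))
    if len(levels) != 2:
        raise ValueError("lda_effect_size requires exactly two groups")
    X = relab.data.fillna(0).to_numpy(dtype=float) * LEFSE_SCALE
    y = (groups.loc[relab.sample_ids].to_numpy() == levels[1]).astype(int)

    # Kruskal-Wallis screen; constant features are skipped
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.unique(col).size < 2:
            continue
        try:
            _, p = kruskal(col[y == 0], col[y == 1])
        except ValueError:
            continue
        if p < alpha:
            keep.append(j)
    if not keep:
        return []
    Xk = X[:, keep]
    names = [relab.feature_ids[j] for j in keep]
    mean_diff = Xk[y == 1].mean(axis=0) - Xk[y == 0].mean(axis=0)

    rng = np.random.default_rng(seed)
    n = len(y)
    scores = np.zeros(Xk.shape[1])
    n_ok = 0
    for _ in range(n_boot):
        idx = np.sort(rng.choice(n, size=max(4, int(n * 2 / 3)), replace=False))
        if np.unique(y[idx]).size < 2:
            continue
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage="auto")
        try:
            lda.fit(Xk[idx], y[idx])
        except np.linalg.LinAlgError:
            continue
        w = lda.scalings_[:, 0]
        w = w / (np.linalg.norm(w) or 1.0)
        ld = Xk[idx] @ w
        eff = abs(ld[y[idx] == 1].mean() - ld[y[idx] == 0].mean())
        md = Xk[idx][y[idx] == 1].mean(axis=0) - Xk[idx][y[idx] == 0].mean(axis=0)
        scores += (np.abs(w) * eff + np.abs(md)) / 2.0
        n_ok += 1
    if n_ok == 0:
        return []
    scores /= n_ok
    lda_scores = np.log10(1.0 + np.abs(scores))
    out = []
    for name, s, d in zip(names, lda_scores, mean_diff):
        if s > threshold:
            out.append(LdaEffect(feature=name, lda_score=float(s),
                                 direction=levels[1] if d > 0 else levels[0]))
    out.sort(key=lambda e: -e.lda_score)
    return out


# ---------------------------------------------------------------------------
# metagenome prediction


def predict_metagenome(counts: FeatureTable, ref: GeneContentReference,
                       strict: bool = True) -> PredictedMetagenome:
    """PICRUSt-style functional prediction from a taxon count table.

    Each taxon's counts are divided by its 16S copy number, the normalised
    table is multiplied by the reference taxon x KO gene-content matrix, and
    KO abundances are summed into pathways (a KO contributes to every
    pathway it maps to; unmapped KOs contribute to none).
    """
    data = counts.data.fillna(0).astype(float)
    missing = sorted(set(data.columns) - set(ref.taxa))
    if missing:
        if strict:
            raise ValueError(f"taxa missing from gene-content reference: {missing}")
        log.warning("dropping %d taxa absent from reference", len(missing))
        data = data.drop(columns=missing)
    taxa = list(data.columns)
    normalised = data / ref.copy_number.loc[taxa]
    ko = normalised.to_numpy() @ ref.ko_content.loc[taxa].to_numpy()
    ko_df = pd.DataFrame(ko, index=data.index, columns=ref.ko_content.columns)
    pw_cols = ref.pathways()
    pw = pd.DataFrame(0.0, index=data.index, columns=pw_cols)
    for ko_id in ko_df.columns:
        for pathway in ref.pathway_map.get(ko_id, ()):
            pw[pathway] += ko_df[ko_id]
    return PredictedMetagenome(
        ko_table=FeatureTable(ko_df, block="gene-set", unit="count"),
        pathway_table=FeatureTable(pw, block="gene-set", unit="count"),
    )
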