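"""Metabolome stage: quantification, detection filter, scaling, ordination,
discriminant analysis and pathway over-representation.

The processing chain mirrors standard CE-TOFMS fecal metabolomics practice:
peak areas are normalised against per-mode internal standards (methionine
sulfone for cations, camphor-10-sulfonic acid for anions) and converted to
concentrations via standard compounds; metabolites detected in at least four
samples of every diet group are retained; remaining not-detected values are
imputed as half the feature minimum; features are Pareto-scaled before PCA
and OPLS-DA.  Enrichment of a significant-metabolite list against a pathway
library uses the hypergeometric upper tail (over-representation analysis).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import bh_fdr, hypergeom_upper_tail
from .tables_io import FeatureTable, PathwayLibrary, SampleMetadata

__all__ = [
    "OrdinationResult",
    "OplsdaResult",
    "quantify",
    "detection_filter",
    "impute_half_minimum",
    "pareto_scale",
    "pca",
    "loading_report",
    "oplsda",
    "msea_ora",
]

log = logging.getLogger(__name__)


@dataclass
class OrdinationResult:
    """Scores, loadings and explained-variance ratios of an ordination."""

    scores: pd.DataFrame            # samples x components
    loadings: pd.DataFrame | None   # features x components (None for PCoA)
    explained_variance_ratio: pd.Series
    eigvals: pd.Series | None = None


@dataclass
class OplsdaResult:
    """Orthogonal PLS discriminant analysis summary.

    ``covariance[j] = cov(x_j, t_pred)`` is the feature-ranking statistic;
    ``q2_cum`` is the cross-validated predictive ability and ``r2x_cum`` the
    fraction of X variance captured by the predictive + orthogonal scores.
    """

    t_pred: pd.Series
    t_orth: pd.DataFrame
    covariance: pd.Series
    q2_cum: float
    r2x_cum: float
    n_orth: int


# ---------------------------------------------------------------------------
# quantification


def quantify(peak_areas: FeatureTable, is_areas: pd.DataFrame,
             standards: pd.DataFrame) -> FeatureTable:
    """Convert peak areas to concentrations via internal standards.

    Parameters
    ----------
    peak_areas : metabolite peak areas (NaN = not detected).
    is_areas : per-sample internal-standard areas, columns ``cationic`` and
        ``anionic``.  A sample with a missing internal-standard area is
        rejected (dropped with a log entry).
    standards : per-metabolite frame with columns ``ion_mode`` (cationic |
        anionic), ``std_rel_area`` (standard compound's area relative to its
        internal standard) and ``std_conc`` (standard concentration).

    conc = (area / IS_area) / std_rel_area * std_conc, per metabolite.
    """
    bad = is_areas.loc[peak_areas.sample_ids].isna().any(axis=1)
    if bad.any():
        log.warning("rejecting %d sample(s) with missing internal-standard "
                    "areas: %s", bad.sum(), list(bad.index[bad]))
    keep = [s for s in peak_areas.sample_ids if not bad.get(s, False)]
    areas = peak_areas.data.loc[keep]
    out = pd.DataFrame(index=areas.index, columns=areas.columns, dtype=float)
    for met in areas.columns:
        mode = standards.loc[met, "ion_mode"]
        is_col = is_areas.loc[keep, mode]
        rel = areas[met] / is_col
        out[met] = rel / standards.loc[met, "std_rel_area"] * standards.loc[met, "std_conc"]
    return FeatureTable(out, block="metabolite", unit="concentration")


# ---------------------------------------------------------------------------
# filtering, imputation, scaling


def detection_filter(tbl: FeatureTable, meta: SampleMetadata,
                     min_per_group: int = 4) -> FeatureTable:
    """Keep metabolites detected in >= ``min_per_group`` samples of *every* group.

    Detection means a non-NaN value; true zeros count as detected.
    """
    groups = meta.groups.loc[tbl.sample_ids]
    for level, sub in tbl.data.groupby(groups):
        if len(sub) < min_per_group:
            raise ValueError(
                f"group {level!r} has only {len(sub)} samples "
                f"(< min_per_group={min_per_group})")
    detected = tbl.data.notna()
    keep = pd.Series(True, index=tbl.data.columns)
    for _, sub in detected.groupby(groups):
        keep &= sub.sum(axis=0) >= min_per_group
    return FeatureTable(tbl.data.loc[:, keep[keep].index], tbl.block, tbl.unit)


def impute_half_minimum(tbl: FeatureTable) -> FeatureTable:
    """Replace not-detected values by half the feature's minimum observed value."""
    data = tbl.data.copy()
    fill = data.min(axis=0, skipna=True) / 2.0
    data = data.fillna(fill)
    return FeatureTable(data, tbl.block, tbl.unit)


def pareto_scale(tbl: FeatureTable) -> FeatureTable:
    """Mean-centre each feature and divide by the square root of its sample SD.

    Zero-variance features are left centred (all zeros) with a warning.
    """
    data = tbl.data
    if data.isna().any().any():
        raise ValueError("pareto_scale requires a complete table; impute first")
    centred = data - data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"{int((sd == 0).sum())} zero-variance feature(s) left "
                      "centred only", RuntimeWarning, stacklevel=2)
    denom = np.sqrt(sd).replace(0.0, 1.0)
    return FeatureTable(centred / denom, tbl.block, unit="scaled")


# ---------------------------------------------------------------------------
# ordination


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Deterministic sign convention: largest-|loading| entry positive."""
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1


def pca(tbl: FeatureTable, n_components: int | None = None) -> OrdinationResult:
    """SVD-based principal component analysis of a scaled table."""
    X = tbl.data.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k = rank if n_components is None else min(n_components, rank)
    scores = U[:, :k] * s[:k]
    loadings = Vt[:k].T.copy()
    _fix_signs(loadings, scores)
    total_var = (s ** 2).sum()
    evr = s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
    comps = [f"PC{i+1}" for i in range(k)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=tbl.data.index, columns=comps),
        loadings=pd.DataFrame(loadings, index=tbl.data.columns, columns=comps),
        explained_variance_ratio=pd.Series(evr, index=comps),
        eigvals=pd.Series(s[:k] ** 2 / (X.shape[0] - 1), index=comps),
    )


def loading_report(result: OrdinationResult, component: str = "PC2",
                   threshold: float = 0.11) -> pd.Series:
    """Features whose |loading coefficient| exceeds the threshold, sorted."""
    coefs = result.loadings[component]
    sel = coefs[coefs.abs() > threshold]
    return sel.sort_values(ascending=False)


# ---------------------------------------------------------------------------
# OPLS-DA (Trygg-Wold NIPALS)


def _opls_fit(X: np.ndarray, y: np.ndarray, n_orth: int):
    """One predictive + ``n_orth`` orthogonal components; y is centred ±1."""
    w = X.T @ y / (y @ y)
    w = w / np.linalg.norm(w)
    W_o, P_o, T_o = [], [], []
    Xf = X.copy()
    for _ in range(n_orth):
        t = Xf @ w
        p = Xf.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break  # no orthogonal variation left
        w_o = w_o / norm
        t_o = Xf @ w_o
        p_o = Xf.T @ t_o / (t_o @ t_o)
        Xf = Xf - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    t_pred = Xf @ w
    c = (y @ t_pred) / (t_pred @ t_pred)
    p_pred = Xf.T @ t_pred / (t_pred @ t_pred)
    return w, c, p_pred, t_pred, W_o, P_o, T_o


def _opls_filter(Xnew: np.ndarray, w, W_o, P_o) -> np.ndarray:
    Xf = Xnew.copy()
    for w_o, p_o in zip(W_o, P_o):
        t_o = Xf @ w_o
        Xf = Xf - np.outer(t_o, p_o)
    return Xf


def oplsda(tbl: FeatureTable, groups: pd.Series, n_orth: int = 1,
           n_folds: int = 7, seed: int | None = 0) -> OplsdaResult:
    """Orthogonal PLS-DA of a scaled table against a two-level grouping.

    Class membership is encoded ±1; class-orthogonal variation is removed by
    NIPALS before a single predictive component is extracted.  Q2 is computed
    by ``n_folds``-fold cross-validation with venetian-blind fold assignment
    after a seeded shuffle of the sample order.
    """
    levels = sorted(pd.unique(groups.loc[tbl.sample_ids]))
    if len(levels) != 2:
        raise ValueError(f"OPLS-DA requires exactly 2 groups, got {levels}")
    X = tbl.data.to_numpy(dtype=float)
    y_raw = np.where(groups.loc[tbl.sample_ids].to_numpy() == levels[1], 1.0, -1.0)
    y = y_raw - y_raw.mean()
    n = X.shape[0]

    w, c, p_pred, t_pred, W_o, P_o, T_o = _opls_fit(X, y, n_orth)

    # covariance of each (original, scaled) feature with the predictive score,
    # which is rescaled to unit variance first (S-plot convention) so the
    # statistic is comparable across models and thresholds are meaningful
    tc = t_pred - t_pred.mean()
    t_sd = tc.std(ddof=1)
    tc = tc / t_sd if t_sd > 0 else tc
    covariance = (X - X.mean(axis=0)).T @ tc / (n - 1)

    # R2X: variance captured by predictive + orthogonal components
    ssx = (X ** 2).sum()
    modelled = np.outer(t_pred, p_pred)
    for t_o, p_o in zip(T_o, P_o):
        modelled += np.outer(t_o, p_o)
    r2x = float((modelled ** 2).sum() / ssx) if ssx > 0 else 0.0

    # Q2 by k-fold CV (venetian blinds over a seeded shuffle)
    folds = min(n_folds, n)
    if folds < n_folds:
        log.warning("reducing CV folds from %d to %d (n=%d)", n_folds, folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    assignment[order] = np.arange(n) % folds
    press, ss = 0.0, float(((y - y.mean()) ** 2).sum())
    for f in range(folds):
        test = assignment == f
        Xtr, ytr = X[~test], y_raw[~test]
        ytr_c = ytr - ytr.mean()
        wf, cf, _, _, Wof, Pof, _ = _opls_fit(Xtr, ytr_c, n_orth)
        Xte = _opls_filter(X[test], wf, Wof, Pof)
        yhat = (Xte @ wf) * cf + ytr.mean()
        press += float(((y_raw[test] - yhat) ** 2).sum())
    q2 = 1.0 - press / ss if ss > 0 else float("nan")

    idx = tbl.data.index
    return OplsdaResult(
        t_pred=pd.Series(t_pred, index=idx, name="t_pred"),
        t_orth=pd.DataFrame(np.column_stack(T_o) if T_o else np.empty((n, 0)),
                            index=idx,
                            columns=[f"t_orth{i+1}" for i in range(len(T_o))]),
        covariance=pd.Series(covariance, index=tbl.data.columns, name="covariance"),
        q2_cum=float(q2),
        r2x_cum=r2x,
        n_orth=len(T_o),
    )


def covariance_report(result: OplsdaResult, threshold: float = 0.16) -> pd.Series:
    """Features whose |OPLS-DA covariance| exceeds the threshold, sorted."""
    cov = result.covariance
    return cov[cov.abs() > threshold].sort_values(ascending=False)


# ---------------------------------------------------------------------------
# enrichment (MSEA, over-representation mode)


def msea_ora(query: set[str] | list[str], lib: PathwayLibrary) -> pd.DataFrame:
    """Pathway over-representation of a significant-metabolite list.

    For each pathway of size K in a universe of N metabolites and a query of
    size n with k hits: expect = K*n/N, fold = k/expect, p = upper
    hypergeometric tail P[X >= k].  Rows are sorted by p (ties broken by
    pathway name); a BH q column is appended for convenience.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query set")
    if lib.universe is not None:
        stray = query - lib.universe
    else:
        members = set().union(*lib.pathways.values()) if lib.pathways else set()
        stray = query - members
        # metabolites outside every pathway are legal universe members; only
        # warn when the universe is explicit
        stray = set() if len(members) < lib.universe_size else stray
    if stray:
        warnings.warn(f"{len(stray)} query metabolite(s) outside the library "
                      "universe were dropped", RuntimeWarning, stacklevel=2)
        query = query - stray
        if not query:
            raise ValueError("no query metabolites remain within the universe")
    N, n = lib.universe_size, len(query)
    rows = []
    for pw, members in lib.pathways.items():
        K = len(members)
        k = len(query & members)
        expect = K * n / N
        fold = k / expect if expect > 0 else 0.0
        p = hypergeom_upper_tail(N, K, n, k) if k > 0 else 1.0
        rows.append((pw, K, k, expect, fold, p))
    out = pd.DataFrame(rows, columns=["pathway", "total", "hits", "expect",
                                      "fold", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "pathway"], kind="mergesort").reset_index(drop=True)
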