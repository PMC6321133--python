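"""Shared statistical primitives used by every analysis stage.

All group comparisons in the pipeline reduce to a two-sided Mann-Whitney U
test with Benjamini-Hochberg FDR control; associations between feature
abundances use Spearman's rank correlation; pathway over-representation uses
the hypergeometric upper tail.  Everything here is a thin, well-specified
layer over scipy, so that each stage shares a single set of conventions
(sidedness, tie handling, NaN propagation) rather than re-deciding them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "mann_whitney_u",
    "bh_fdr",
    "spearman_rho",
    "hypergeom_upper_tail",
    "differential_table",
]

#: combined sample size at or below which the exact MWU null is used
EXACT_MWU_MAX_N = 12


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact permutation null when the pooled sample size is at most
    ``EXACT_MWU_MAX_N`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  Returns ``(U, p)``
    where U is the statistic for ``x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must contain at least one observation")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                            use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries propagate as NaN and are excluded from the family size.
    Output is capped at 1.  Cross-checked against
    ``statsmodels.stats.multitest.multipletests`` in the test suite.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pm = p[mask]
    if pm.size and ((pm < 0).any() or (pm > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    m = pm.size
    if m:
        order = np.argsort(pm, kind="mergesort")
        scaled = pm[order] * m / np.arange(1, m + 1)
        qv = np.minimum.accumulate(scaled[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(qv, 1.0)
        q[mask] = out
    return q


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    The p-value uses the t-distribution approximation with n-2 degrees of
    freedom (scipy's default), which is adequate for the sample sizes this
    pipeline sees (n >= 10 in practice, n >= 3 enforced here).  A zero-variance
    argument makes rho undefined: ``(nan, nan)`` is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        warnings.warn("constant input: Spearman rho undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan"), float("nan")
    res = _sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the category ("pathway") size, n the query size
    and k the observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K <= N and 0 <= n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    return float(_sps.hypergeom.sf(k - 1, N, K, n))


def differential_table(data: pd.DataFrame, groups: pd.Series,
                       levels: tuple[str, str] = ("control", "AD"),
                       subjects: pd.Series | None = None) -> pd.DataFrame:
    """Per-feature two-group Mann-Whitney U + BH FDR + fold change.

    Parameters
    ----------
    data : samples x features frame.  NaN (not-detected) values are treated
        as zeros for both the rank test and the group means, i.e. below the
        detection limit counts as the lowest abundance.
    groups : group label per sample, aligned with ``data``'s index.
    levels : (reference, case).  Fold change is mean(case)/mean(reference);
        it is NaN (rendered "-" in reports) when the reference mean is zero.
    subjects : optional subject id per sample.  When given, repeated
        measurements are averaged per subject before testing (one value per
        animal), the conservative alternative to pooling timepoints.

    Returns a frame indexed by feature with columns
    ``U, p, q, mean_<ref>, mean_<case>, fold_change``.
    """
    ref, case = levels
    if subjects is not None:
        subjects = subjects.loc[data.index]
        data = data.fillna(0.0).groupby(subjects).mean()
        groups = groups.loc[subjects.index].groupby(subjects).first()
    g = groups.loc[data.index]
    x_mask = (g == case).to_numpy()
    y_mask = (g == ref).to_numpy()
    if x_mask.sum() == 0 or y_mask.sum() == 0:
        raise ValueError(f"both group levels {levels} must be present")
    filled = data.to_numpy(dtype=float)
    filled = np.where(np.isnan(filled), 0.0, filled)

    rows = []
    for j, feat in enumerate(data.columns):
        col = filled[:, j]
        u, p = mann_whitney_u(col[x_mask], col[y_mask])
        rows.append((feat, u, p, col[y_mask].mean(), col[x_mask].mean()))
    out = pd.DataFrame(rows, columns=["feature", "U", "p", f"mean_{ref}",
                                      f"mean_{case}"]).set_index("feature")
    out["q"] = bh_fdr(out["p"].to_numpy())
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = out[f"mean_{case}"] / out[f"mean_{ref}"]
    out["fold_change"] = fc.where(out[f"mean_{ref}"] > 0, np.nan)
    return out[["U", "p", "q", f"mean_{ref}", f"mean_{case}", "fold_change"]]


def format_fold_change(fc: float, ndigits: int = 2) -> str:
    """Render a fold change for reports: 2 decimals, '-' when undefined."""
    if fc is None or (isinstance(fc, float) and np.isnan(fc)):
        return "-"
    return f"{fc:.{ndigits}f}"
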