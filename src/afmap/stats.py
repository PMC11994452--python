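"""Shared statistical primitives.

These are the rank-based specificity AUC (one-vs-rest Wilcoxon rank-sum
with midranks), Benjamini-Hochberg FDR, library-size log-normalization
and Pearson correlation with its t-based p-value.  All are implemented
from first principles; the test suite checks them against independent
oracles (brute-force pair counting, the textbook step-up definition,
scipy reference routines).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from afmap.datamodel import SparseCountMatrix


def log_normalize(counts: SparseCountMatrix, scale: float = 1e4) -> SparseCountMatrix:
    """Library-size normalize then log1p: ``ln(1 + scale * c / rowTotal)``.

    Zeros map to zero, so sparsity is preserved.  An observation with a
    zero total has no defined library size and raises.
    """
    totals = np.asarray(counts.matrix.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = counts.obs_ids[int(np.flatnonzero(totals == 0)[0])]
        raise ValueError(f"observation {bad!r} has zero total count")
    mat = counts.matrix.tocsr().astype(np.float64, copy=True)
    row_scale = scale / totals
    mat.data *= np.repeat(row_scale, np.diff(mat.indptr))
    np.log1p(mat.data, out=mat.data)
    out = SparseCountMatrix.__new__(SparseCountMatrix)
    out.matrix = mat
    out.obs_ids = list(counts.obs_ids)
    out.feature_ids = list(counts.feature_ids)
    return out


def _tie_term(ranks: np.ndarray) -> np.ndarray:
    """Per-feature tie correction sum(t^3 - t) over tie groups."""
    tie = np.empty(ranks.shape[1])
    for j in range(ranks.shape[1]):
        _, cnt = np.unique(ranks[:, j], return_counts=True)
        tie[j] = np.sum(cnt.astype(np.float64) ** 3 - cnt)
    return tie


def _auc_from_ranks(ranks: np.ndarray, in_group: np.ndarray, tie_term: np.ndarray | None = None):
    """AUC and tie-corrected normal-approximation p from shared midranks.

    ``ranks`` is observations x features (midranks within each feature
    column); returns per-feature AUC and two-sided p for the one-vs-rest
    rank-sum test of ``in_group`` against its complement.  ``tie_term``
    does not depend on the grouping and may be precomputed.
    """
    n = ranks.shape[0]
    n1 = int(in_group.sum())
    n2 = n - n1
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0  # Mann-Whitney U of the in-group
    auc = u / (n1 * n2)

    if tie_term is None:
        tie_term = _tie_term(ranks)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (u - n1 * n2 / 2.0) / np.sqrt(var_u)
    p = np.where(var_u > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    # constant feature: all ties, AUC 0.5 by construction of midranks
    return auc, p


def rank_auc_test(
    values: np.ndarray | sp.spmatrix,
    groups: np.ndarray | list,
    group: str,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum specificity test for one group.

    Parameters
    ----------
    values
        Observations x features matrix of (normalized) values.
    groups
        Group label per observation.
    group
        The in-group whose specificity is scored against all others.

    Returns
    -------
    DataFrame with columns ``feature, group, auc, p, fdr, pct_in,
    pct_out``.  AUC = U / (n1 * n2) with ties counted half; p from the
    normal approximation with tie-corrected variance; FDR is BH across
    features within this contrast.
    """
    groups = np.asarray(groups)
    in_group = groups == group
    if in_group.sum() == 0:
        raise ValueError(f"group {group!r} has no members")
    if in_group.sum() == len(groups):
        raise ValueError(f"group {group!r} has an empty complement")
    dense = np.asarray(values.todense()) if sp.issparse(values) else np.asarray(values)
    ranks = rankdata(dense, axis=0)
    return _finish_auc(dense, ranks, in_group, group, feature_ids=None)


def _finish_auc(dense, ranks, in_group, group, feature_ids, tie_term=None) -> pd.DataFrame:
    auc, p = _auc_from_ranks(ranks, in_group, tie_term)
    out = pd.DataFrame(
        {
            "feature": feature_ids
            if feature_ids is not None
            else np.arange(dense.shape[1]),
            "group": group,
            "auc": auc,
            "p": p,
            "fdr": bh_fdr(p),
            "pct_in": (dense[in_group] != 0).mean(axis=0),
            "pct_out": (dense[~in_group] != 0).mean(axis=0),
        }
    )
    return out


def auc_specificity_all_groups(
    counts_or_values,
    groups: np.ndarray | list,
    feature_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Run the one-vs-rest AUC test for every group label.

    Ranks are computed once and shared across contrasts (they do not
    depend on the grouping).  Accepts a :class:`SparseCountMatrix` of
    normalized values or a plain matrix.
    """
    if isinstance(counts_or_values, SparseCountMatrix):
        feature_ids = counts_or_values.feature_ids
        dense = counts_or_values.to_dense()
    else:
        dense = (
            np.asarray(counts_or_values.todense())
            if sp.issparse(counts_or_values)
            else np.asarray(counts_or_values)
        )
    groups = np.asarray(groups)
    ranks = rankdata(dense, axis=0)
    tie = _tie_term(ranks)
    frames = []
    for g in sorted(pd.unique(groups)):
        in_group = groups == g
        if in_group.all():
            raise ValueError("a single group covers all observations")
        frames.append(_finish_auc(dense, ranks, in_group, g, feature_ids, tie))
    return pd.concat(frames, ignore_index=True)


def bh_fdr(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    clipped at 1.  NaNs propagate and are excluded from ``m``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Pearson r with a two-sided t-based p-value.

    Returns ``(r, p, ok)``; ``ok`` is False (with NaN r and p) when
    either vector has zero variance.  ``|r| = 1`` maps to p = 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        return float("nan"), float("nan"), False
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0, True
    t = r * np.sqrt((n - 2) / (1 - r * r))
    from scipy.stats import t as t_dist

    p = float(2.0 * t_dist.sf(abs(t), df=n - 2))
    return r, p, True
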