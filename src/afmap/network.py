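"""Signed weighted-coexpression modules (simplified WGCNA).

Pipeline: filter genes on a merged-cohort DE table (base mean > 1,
|log2FC| > 0.05, nominal p < 0.05), residualize nuisance covariates
(sex, dataset) out of the variance-stabilized expression, build the
signed adjacency a_ij = ((1 + cor_ij)/2)^power, take the topological
overlap, cluster average-linkage on 1 - TOM with a static tree cut,
drop undersized clusters to the unassigned label 0, and iteratively
merge modules whose eigengenes correlate above 1 - mergeCutHeight.

The static cut replaces the reference dynamic tree cut; correctness is
defined by planted-module recovery tests rather than equivalence to the
reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform


@dataclass
class ModulePartition:
    """Gene -> module label (0 = unassigned) plus sample x module eigengenes."""

    labels: pd.Series
    eigengenes: pd.DataFrame


def prefilter_genes(
    de_merged: pd.DataFrame,
    base_mean_min: float = 1.0,
    lfc_min: float = 0.05,
    p_max: float = 0.05,
) -> list[str]:
    """Genes passing all three strict filters on the merged-cohort DE table."""
    ok = (
        (de_merged["base_mean"] > base_mean_min)
        & (np.abs(de_merged["log2fc"]) > lfc_min)
        & (de_merged["p"] < p_max)
    )
    return de_merged.loc[ok.fillna(False), "gene_id"].tolist()


def residualize_covariates(expr: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Remove covariate effects per gene by least squares.

    ``expr`` is samples x genes (already variance-stabilized);
    ``covariates`` holds numeric design columns (no intercept, no
    condition).  Covariates are centered before fitting so the grand
    mean of every gene is preserved; per-gene fitted covariate terms
    are subtracted.
    """
    C = covariates.to_numpy(dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    Cc = C - C.mean(axis=0)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(Cc)), Cc])) <= Cc.shape[1]:
        raise ValueError("a covariate is collinear with the intercept (constant?)")
    Y = expr.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(Cc, Y - Y.mean(axis=0), rcond=None)
    return pd.DataFrame(Y - Cc @ beta, index=expr.index, columns=expr.columns)


def signed_adjacency(expr: pd.DataFrame, power: int = 9) -> pd.DataFrame:
    """Signed network adjacency ((1 + cor)/2)^power, genes x genes."""
    Y = expr.to_numpy(dtype=float)
    if Y.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    sd = Y.std(axis=0)
    if (sd == 0).any():
        bad = expr.columns[int(np.flatnonzero(sd == 0)[0])]
        raise ValueError(f"constant gene {bad!r} has undefined correlation")
    cor = np.corrcoef(Y, rowvar=False)
    cor = np.clip(cor, -1.0, 1.0)
    a = (0.5 * (1.0 + cor)) ** power
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=expr.columns, columns=expr.columns)


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap matrix of a signed adjacency.

    TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    L_ij = sum_u a_iu a_uj and k_i = sum_u a_iu, sums excluding i and j;
    diagonal is 1.
    """
    A = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(A, 0.0)
    L = A @ A
    k = A.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def module_eigengene(expr: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component of each module's standardized expression.

    The sign is oriented so the eigengene correlates positively with
    the module's mean expression profile; a single-gene module returns
    that gene's standardized profile.  Deterministic (LAPACK SVD).
    """
    eig = {}
    for mod in sorted(set(labels) - {0}):
        genes = labels.index[labels == mod]
        sub = expr[genes].to_numpy(dtype=float)
        sd = sub.std(axis=0)
        z = (sub - sub.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        if z.shape[1] == 1:
            e = z[:, 0]
        else:
            u, s, _ = np.linalg.svd(z, full_matrices=False)
            e = u[:, 0] * s[0] / np.sqrt(max(z.shape[0] - 1, 1))
        mean_profile = z.mean(axis=1)
        if np.dot(e, mean_profile) < 0:
            e = -e
        eig[f"ME{mod}"] = e
    return pd.DataFrame(eig, index=expr.index)


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 50,
    cut_height: float = 0.8,
    merge_cut_height: float = 0.25,
) -> ModulePartition:
    """Static-cut module detection on 1 - TOM with eigengene merging.

    Average-linkage hierarchical clustering of the TOM dissimilarity is
    cut at ``cut_height`` of the merge-height range (the default 0.8
    sits between within-module merges and the late attachment of
    background genes across a wide range of signal strengths); clusters
    below ``min_module_size`` fall into label 0; modules whose
    eigengenes correlate above ``1 - merge_cut_height`` are merged,
    iterated to a fixed point.  Labels are renumbered 1..K by
    decreasing module size.
    """
    if not (0.0 < cut_height < 1.0):
        raise ValueError("cut_height must lie in (0, 1)")
    genes = tom.index
    d = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    h = heights.min() + cut_height * (heights.max() - heights.min())
    raw = fcluster(Z, t=h, criterion="distance")

    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    small = sizes.index[sizes < min_module_size]
    labels[labels.isin(small)] = 0

    labels = _renumber(labels)
    # iterative eigengene merging
    while True:
        mods = sorted(set(labels) - {0})
        if len(mods) < 2:
            break
        eig = module_eigengene(expr, labels)
        cor = np.corrcoef(eig.to_numpy(), rowvar=False)
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_cut_height:
            break
        a, b = mods[i], mods[j]
        labels[labels == b] = a
        labels = _renumber(labels)
    return ModulePartition(labels=labels, eigengenes=module_eigengene(expr, labels))


def _renumber(labels: pd.Series) -> pd.Series:
    """Relabel modules 1..K by decreasing size (stable tie-break)."""
    sizes = labels[labels != 0].value_counts()
    mapping = {old: new for new, old in enumerate(sizes.index, start=1)}
    mapping[0] = 0
    return labels.map(mapping)
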