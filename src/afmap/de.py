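"""Bulk and pseudobulk differential expression (AF vs SR).

The engine is a negative-binomial GLM with log link, median-of-ratios
size-factor offsets and a Wald test on the condition coefficient, fitted
by IRLS vectorized across genes.  Dispersion is a per-gene
method-of-moments estimate on normalized counts (no empirical-Bayes
shrinkage) and the reported log2 fold change is the unshrunken MLE;
both are deliberate simplifications of the reference bulk-RNA-seq
workflow and are validated by calibration and recovery simulations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from afmap.datamodel import SparseCountMatrix, make_de_table
from afmap.stats import bh_fdr

MIN_DISPERSION = 1e-8


def size_factors(counts: SparseCountMatrix | np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (samples x genes input).

    For genes positive in every sample, factor_s = median_g of
    c_gs / geometric-mean_g(c_g.).
    """
    dense = counts.to_dense() if isinstance(counts, SparseCountMatrix) else np.asarray(counts)
    if dense.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    all_pos = (dense > 0).all(axis=0)
    if not all_pos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "pseudo-reference fallback is not enabled"
        )
    ref = dense[:, all_pos].astype(np.float64)
    log_geo = np.log(ref).mean(axis=0)
    return np.exp(np.median(np.log(ref) - log_geo[None, :], axis=1))


def _dispersion_mom(norm_counts: np.ndarray, groups: np.ndarray | None = None) -> np.ndarray:
    """Per-gene method-of-moments dispersion on normalized counts.

    alpha_hat = max((s^2 - mu) / mu^2, 1e-8).  When ``groups`` is given
    the moments are taken within each group and pooled (weights n_k - 1)
    so a real condition effect does not inflate the dispersion.
    """

    def mom(x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=0)
        s2 = x.var(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (s2 - mu) / mu**2
        return np.where(np.isfinite(a), a, 0.0)

    if groups is None:
        alpha = mom(norm_counts)
    else:
        groups = np.asarray(groups)
        num = np.zeros(norm_counts.shape[1])
        den = 0.0
        for g in pd.unique(groups):
            sub = norm_counts[groups == g]
            if sub.shape[0] < 2:
                continue
            w = sub.shape[0] - 1
            num += w * mom(sub)
            den += w
        alpha = num / den if den > 0 else mom(norm_counts)
    return np.maximum(alpha, MIN_DISPERSION)


def _design_matrix(sample_table: pd.DataFrame, contrast: str, covariates: list[str]):
    cond = sample_table[contrast].to_numpy()
    levels = sorted(pd.unique(cond))
    if len(levels) < 2:
        raise ValueError(f"{contrast!r} is constant across samples")
    # AF coded 1 against SR when present, otherwise last level vs first
    test_level = "AF" if "AF" in levels else levels[-1]
    cols = {"intercept": np.ones(len(cond)), contrast: (cond == test_level).astype(float)}
    for cv in covariates:
        cols[cv] = pd.to_numeric(sample_table[cv]).to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the collinear columns by leave-one-out rank check
        bad = [
            names[j]
            for j in range(1, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == np.linalg.matrix_rank(X)
        ]
        raise ValueError(f"design matrix is not full rank; collinear columns: {bad}")
    return X, names, test_level


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
             n_iter: int = 50, tol: float = 1e-8):
    """Vectorized-across-genes IRLS for the NB log-link GLM.

    y: genes x samples; X: samples x p; offset: samples (log scale);
    alpha: genes.  Returns (beta, se) with shapes (genes, p).
    """
    G, n = y.shape
    p = X.shape[1]
    # init from OLS on log pseudo-counts
    ylog = np.log((y + 0.5) / np.exp(offset)[None, :])
    beta, *_ = np.linalg.lstsq(X, ylog.T, rcond=None)
    beta = beta.T  # genes x p
    XT = X.T
    for _ in range(n_iter):
        eta = offset[None, :] + beta @ XT
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + alpha[:, None] * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        A = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
        b = np.einsum("gn,gn,np->gp", w, z, X, optimize=True)
        A += np.eye(p)[None, :, :] * 1e-10
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        step = np.abs(new_beta - beta).max()
        beta = new_beta
        if step < tol:
            break
    eta = offset[None, :] + beta @ XT
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    w = mu / (1.0 + alpha[:, None] * mu)
    A = np.einsum("gn,np,nq->gpq", w, X, X, optimize=True)
    A += np.eye(p)[None, :, :] * 1e-10
    cov = np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=1, axis2=2), 0.0))
    return beta, se


def nb_glm_de(
    counts: SparseCountMatrix,
    sample_table: pd.DataFrame,
    contrast: str = "condition",
    covariates: list[str] | None = None,
    dispersion: float | None = None,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the condition effect.

    Returns a DE table with ``log2fc`` (condition coefficient / ln 2),
    its SE, Wald z, two-sided normal p and BH FDR across tested genes;
    ``base_mean`` is the mean of size-factor-normalized counts.  Genes
    with all counts zero get a missing-statistic row excluded from the
    FDR denominator.  ``dispersion`` overrides the per-gene moments
    estimate with a fixed value (0 gives the Poisson limit).
    """
    covariates = list(covariates or [])
    samples = sample_table.set_index("sample_id").loc[counts.obs_ids].reset_index()
    vc = samples[contrast].value_counts()
    if (vc < 2).any():
        raise ValueError(f"need >=2 samples per {contrast} level, got {vc.to_dict()}")
    X, names, _ = _design_matrix(samples, contrast, covariates)
    j = names.index(contrast)

    dense = counts.to_dense().astype(np.float64)
    sf = size_factors(counts)
    norm_counts = dense / sf[None, :].T
    base_mean = norm_counts.mean(axis=0)
    testable = (dense.sum(axis=0) > 0)

    G = dense.shape[1]
    log2fc = np.full(G, np.nan)
    se_out = np.full(G, np.nan)
    stat = np.full(G, np.nan)
    p = np.full(G, np.nan)
    if testable.any():
        y = dense[:, testable].T  # genes x samples
        if dispersion is None:
            alpha = _dispersion_mom(norm_counts[:, testable], samples[contrast].to_numpy())
        else:
            alpha = np.full(int(testable.sum()), max(dispersion, MIN_DISPERSION))
        beta, se = _irls_nb(y, X, np.log(sf), alpha)
        ln2 = np.log(2.0)
        log2fc[testable] = beta[:, j] / ln2
        se_out[testable] = se[:, j] / ln2
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta[:, j] / se[:, j]
        stat[testable] = z
        p[testable] = 2.0 * norm.sf(np.abs(z))
    return make_de_table(
        gene_id=counts.feature_ids,
        base_mean=base_mean,
        log2fc=log2fc,
        se=se_out,
        stat=stat,
        p=p,
        fdr=bh_fdr(p),
    )


def pseudobulk_aggregate(
    gene_counts: SparseCountMatrix,
    nucleus_table: pd.DataFrame,
    min_frac: float = 0.05,
) -> dict[str, dict]:
    """Sum nucleus counts per donor within each cell type.

    For each cell type, genes detected (nonzero) in <= ``min_frac`` of
    that cell type's nuclei are dropped from that cell type's table
    (the "found in more than 5% of nuclei" filter).  Cell types with
    fewer than 2 donors in either condition are flagged untestable.

    Returns ``{cell_type: {"counts": SparseCountMatrix(donors x genes),
    "samples": sample table, "testable": bool}}``.
    """
    nt = nucleus_table.set_index("nucleus_id").loc[gene_counts.obs_ids]
    out: dict[str, dict] = {}
    mat = gene_counts.matrix.tocsr()
    for ct in sorted(nt["cell_type"].unique()):
        mask = (nt["cell_type"] == ct).to_numpy()
        sub = mat[mask]
        donors = nt.loc[mask, "donor_id"].to_numpy()
        conds = nt.loc[mask, "condition"].to_numpy()
        detect_frac = np.asarray((sub > 0).mean(axis=0)).ravel()
        keep = detect_frac > min_frac
        donor_ids = sorted(pd.unique(donors))
        rows = []
        donor_cond = []
        for d in donor_ids:
            dm = donors == d
            rows.append(np.asarray(sub[dm].sum(axis=0)).ravel())
            donor_cond.append(conds[dm][0])
        pb = np.vstack(rows)[:, keep].astype(np.int64)
        samples = pd.DataFrame({"sample_id": donor_ids, "condition": donor_cond})
        testable = (
            samples["condition"].value_counts().reindex(["AF", "SR"]).fillna(0) >= 2
        ).all()
        if not testable:
            warnings.warn(f"cell type {ct!r} has <2 donors in a condition; untestable")
        out[ct] = {
            "counts": SparseCountMatrix(
                sp.csr_matrix(pb),
                donor_ids,
                [g for g, k in zip(gene_counts.feature_ids, keep) if k],
            ),
            "samples": samples,
            "testable": bool(testable),
        }
    return out


def concordant_degs(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    fdr: float = 0.05,
    mode: str = "both",
) -> pd.DataFrame:
    """Genes differentially expressed with concordant direction in two cohorts.

    ``mode="both"`` (default): FDR < threshold in *both* tables and the
    same fold-change sign.  ``mode="either"``: FDR < threshold in at
    least one, same sign in both.
    """
    m = de1.set_index("gene_id").join(
        de2.set_index("gene_id"), how="inner", lsuffix="_1", rsuffix="_2"
    )
    if m.empty:
        warnings.warn("empty gene intersection between DE tables")
    sig1 = m["fdr_1"] < fdr
    sig2 = m["fdr_2"] < fdr
    same_sign = np.sign(m["log2fc_1"]) == np.sign(m["log2fc_2"])
    nonzero = (m["log2fc_1"] != 0) & (m["log2fc_2"] != 0)
    if mode == "both":
        keep = sig1 & sig2 & same_sign & nonzero
    elif mode == "either":
        keep = (sig1 | sig2) & same_sign & nonzero
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out = m.loc[keep, ["log2fc_1", "fdr_1", "log2fc_2", "fdr_2"]].copy()
    out["sign"] = np.sign(out["log2fc_1"]).astype(int)
    return out.reset_index().sort_values("gene_id").reset_index(drop=True)


def assign_degs_to_celltypes(
    bulk_concordant: pd.DataFrame,
    per_celltype_de: dict[str, pd.DataFrame],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """For each concordant bulk DEG, list cell types supporting it.

    A cell type supports a gene when its pseudobulk DE has FDR below
    threshold and the fold-change sign agrees with the bulk sign.
    Genes supported nowhere are retained with an empty assignment.
    """
    records = []
    for _, row in bulk_concordant.iterrows():
        gene, sign = row["gene_id"], row["sign"]
        hits = []
        for ct in sorted(per_celltype_de):
            tab = per_celltype_de[ct]
            sub = tab.loc[tab["gene_id"] == gene]
            if sub.empty:
                continue
            r = sub.iloc[0]
            if r["fdr"] < fdr and np.sign(r["log2fc"]) == sign:
                hits.append(ct)
        records.append(
            {"gene_id": gene, "sign": int(sign), "cell_types": ",".join(hits),
             "n_celltypes": len(hits)}
        )
    return pd.DataFrame(records, columns=["gene_id", "sign", "cell_types", "n_celltypes"])


def strand_artifact_check(
    de_stranded: pd.DataFrame,
    de_unstranded: pd.DataFrame,
    antisense_pairs: list[tuple[str, str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Flag likely strand artifacts at overlapping antisense gene pairs.

    A gene is flagged when it is significant in the unstranded analysis
    but not in the stranded one - the hallmark of signal bleeding over
    from an overlapping opposite-strand partner.
    """
    s = de_stranded.set_index("gene_id")
    u = de_unstranded.set_index("gene_id")
    records = []
    for ga, gb in antisense_pairs:
        if ga not in s.index or gb not in s.index or ga not in u.index or gb not in u.index:
            warnings.warn(f"antisense pair ({ga}, {gb}) absent from DE tables; skipped")
            continue
        for gene, partner in ((ga, gb), (gb, ga)):
            fdr_s = float(s.loc[gene, "fdr"])
            fdr_u = float(u.loc[gene, "fdr"])
            records.append(
                {
                    "gene_id": gene,
                    "partner": partner,
                    "fdr_stranded": fdr_s,
                    "fdr_unstranded": fdr_u,
                    "flagged": bool(fdr_u < fdr and not fdr_s < fdr),
                }
            )
    return pd.DataFrame(
        records, columns=["gene_id", "partner", "fdr_stranded", "fdr_unstranded", "flagged"]
    )
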