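"""AF expression signatures: construction, module scoring, target ranking.

A cell-type-specific AF signature is the three-way intersection of
(1) genes specifically expressed in the target cell type (one-vs-rest
AUC > 0.5 at FDR < 5%), (2) genes differentially expressed in bulk
cohort 1 and (3) in bulk cohort 2 (FDR < 0.05, |log2FC| > 0.25), split
by direction of effect.  Cells or meta-cells are scored with a
binned-control module score (signature mean minus expression-matched
control mean), and candidate target genes are ranked by the product of
their cell-type-specificity AUC and condition AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from afmap.datamodel import SignatureSet, SparseCountMatrix


@dataclass
class ModuleScoreParams:
    """Binned-control scoring parameters (reference-implementation defaults)."""

    n_bins: int = 24
    n_ctrl: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.n_ctrl < 1:
            raise ValueError("n_ctrl must be >= 1")


def build_af_signature(
    spec_auc: pd.DataFrame,
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    name: str = "AF_CM",
    auc_min: float = 0.5,
    spec_fdr: float = 0.05,
    de_fdr: float = 0.05,
    lfc_min: float = 0.25,
) -> SignatureSet:
    """Intersect cell-type specificity with two-cohort differential expression.

    Parameters
    ----------
    spec_auc
        One-vs-rest AUC table for the target cell type (columns
        ``feature, auc, fdr``).
    de1, de2
        Bulk DE tables for the two cohorts.

    The AUC filter is strict (``auc > auc_min``); an empty signature is
    returned with a warning, not an error.
    """
    spec_ok = spec_auc.loc[
        (spec_auc["auc"] > auc_min) & (spec_auc["fdr"] < spec_fdr), "feature"
    ]
    specific = set(spec_ok)

    def de_dir(tab: pd.DataFrame, sign: int) -> set[str]:
        ok = (tab["fdr"] < de_fdr) & (np.abs(tab["log2fc"]) > lfc_min) & (
            np.sign(tab["log2fc"]) == sign
        )
        return set(tab.loc[ok, "gene_id"])

    up = specific & de_dir(de1, 1) & de_dir(de2, 1)
    down = specific & de_dir(de1, -1) & de_dir(de2, -1)
    if not up and not down:
        warnings.warn(f"signature {name!r} is empty at the given thresholds")
    return SignatureSet(
        name=name,
        up_genes=up,
        down_genes=down,
        thresholds={
            "auc_min": auc_min,
            "spec_fdr": spec_fdr,
            "de_fdr": de_fdr,
            "lfc_min": lfc_min,
        },
    )


def module_score(
    norm_expr: SparseCountMatrix,
    gene_set: set[str] | list[str],
    params: ModuleScoreParams | None = None,
) -> pd.Series:
    """Binned-control module score per observation.

    All genes are binned into ``n_bins`` equal-frequency bins of mean
    expression; for each signature gene, ``n_ctrl`` control genes are
    drawn (with replacement) from its bin, excluding the gene itself
    when the bin offers alternatives.  The score is the mean expression
    of the signature genes minus the mean expression of the pooled
    controls, per observation.  Deterministic given ``params.seed``.
    """
    params = params or ModuleScoreParams()
    genes = sorted(set(map(str, gene_set)))
    if not genes:
        raise ValueError("empty gene set")
    pos = {g: i for i, g in enumerate(norm_expr.feature_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise ValueError(f"genes absent from the matrix: {missing}")

    dense = norm_expr.to_dense()
    mean_expr = dense.mean(axis=0)
    order = np.argsort(mean_expr, kind="mergesort")
    n_bins = min(params.n_bins, len(mean_expr))
    bin_of = np.empty(len(mean_expr), dtype=int)
    # equal-frequency bins over the mean-expression ranking
    bin_of[order] = np.minimum(
        (np.arange(len(order)) * n_bins) // len(order), n_bins - 1
    )
    rng = np.random.default_rng(params.seed)
    bin_members = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}

    sig_idx = np.array([pos[g] for g in genes])
    ctrl_sum = np.zeros(dense.shape[0])
    n_ctrl_total = 0
    for gi in sig_idx:
        members = bin_members[bin_of[gi]]
        candidates = members[members != gi] if len(members) > 1 else members
        draw = rng.choice(candidates, size=params.n_ctrl, replace=True)
        ctrl_sum += dense[:, draw].sum(axis=1)
        n_ctrl_total += params.n_ctrl
    score = dense[:, sig_idx].mean(axis=1) - ctrl_sum / n_ctrl_total
    return pd.Series(score, index=norm_expr.obs_index(), name="module_score")


def rank_target_genes(
    celltype_auc: pd.DataFrame,
    condition_auc: pd.DataFrame,
    signature: SignatureSet,
) -> pd.DataFrame:
    """Rank up-signature genes by cell-type AUC x condition AUC.

    ``celltype_auc`` scores specificity of expression to the target
    cell type across all nuclei; ``condition_auc`` scores AF vs SR
    within that cell type's meta-cells.  Ties break lexicographically
    on gene id; genes lacking an AUC rank last with a missing flag.
    """
    ct = celltype_auc.set_index("feature")["auc"]
    cd = condition_auc.set_index("feature")["auc"]
    rows = []
    for g in sorted(signature.up_genes):
        a1 = float(ct[g]) if g in ct.index else np.nan
        a2 = float(cd[g]) if g in cd.index else np.nan
        score = a1 * a2
        rows.append(
            {
                "gene_id": g,
                "auc_celltype": a1,
                "auc_condition": a2,
                "score": score,
                "missing": not np.isfinite(score),
            }
        )
    out = pd.DataFrame(rows, columns=["gene_id", "auc_celltype", "auc_condition",
                                      "score", "missing"])
    out = out.sort_values(
        ["missing", "score", "gene_id"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
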