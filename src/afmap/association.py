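"""Driver-TF selection: signature vs motif activity and TF expression.

Across CM meta-cells, the AF signature score is correlated (Pearson,
with BH FDR within each arm) against every motif's deviation z-score
and every candidate TF's expression.  A TF is a dual-evidence driver
when both arms are significant; anti-correlation counts (the sign of r
is retained).  Cell-type-level TF prioritization multiplies the
expression AUC and the motif-activity AUC.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from afmap.stats import bh_fdr, pearson_corr


def correlate_with_signature(
    scores: pd.Series,
    predictors: pd.DataFrame,
    exclude: set[str] | list[str] | None = None,
) -> pd.DataFrame:
    """Correlate each predictor column with the signature score.

    ``scores`` and ``predictors`` are indexed by meta-cell id; the
    meta-cells in ``exclude`` (e.g. an outlier donor's) are dropped
    before computing Pearson r.  Zero-variance predictors are reported
    with missing r/p and excluded from the FDR denominator.
    """
    exclude = set(exclude or ())
    keep = [m for m in scores.index if m not in exclude]
    if len(keep) < 3:
        raise ValueError("fewer than 3 meta-cells after exclusion")
    s = scores.loc[keep].to_numpy(dtype=float)
    pred = predictors.loc[keep]
    rows = []
    for col in pred.columns:
        x = pred[col].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            rows.append({"predictor": col, "r": np.nan, "p": np.nan, "ok": False})
            continue
        r, p, ok = pearson_corr(x, s)
        rows.append({"predictor": col, "r": r, "p": p, "ok": ok})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].where(out["ok"]).to_numpy())
    return out


def select_driver_tfs(
    corr_motif: pd.DataFrame,
    corr_expr: pd.DataFrame,
    motif_tf: dict[str, str] | None = None,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Flag TFs significant in both the motif and the expression arm.

    ``corr_motif`` has predictors that are motif ids, ``corr_expr``
    predictors that are TF gene ids; ``motif_tf`` maps motif -> gene so
    the arms can be joined (identity map if omitted).  TFs present in
    only one arm are excluded with a note column.
    """
    motif_tf = motif_tf or {m: m for m in corr_motif["predictor"]}
    cm = corr_motif.set_index("predictor")
    ce = corr_expr.set_index("predictor")
    rows = []
    for motif, tf in sorted(motif_tf.items()):
        if motif not in cm.index or tf not in ce.index:
            rows.append(
                {"tf": tf, "motif": motif, "r_motif": np.nan, "fdr_motif": np.nan,
                 "r_expr": np.nan, "fdr_expr": np.nan, "joint_flag": False,
                 "note": "missing in one arm"}
            )
            continue
        rm, fm = float(cm.loc[motif, "r"]), float(cm.loc[motif, "fdr"])
        re_, fe = float(ce.loc[tf, "r"]), float(ce.loc[tf, "fdr"])
        flag = bool(np.isfinite(fm) and np.isfinite(fe) and fm < fdr_max and fe < fdr_max)
        rows.append(
            {"tf": tf, "motif": motif, "r_motif": rm, "fdr_motif": fm,
             "r_expr": re_, "fdr_expr": fe, "joint_flag": flag, "note": ""}
        )
    return pd.DataFrame(
        rows,
        columns=["tf", "motif", "r_motif", "fdr_motif", "r_expr", "fdr_expr",
                 "joint_flag", "note"],
    )


def rank_tfs_by_specificity(
    gene_auc: pd.DataFrame,
    motif_auc: pd.DataFrame,
    motif_tf: dict[str, str],
) -> pd.DataFrame:
    """Per cell type, rank TFs by expression AUC x motif-activity AUC.

    ``gene_auc`` / ``motif_auc`` are AUC tables with columns
    ``feature, group, auc`` (features: genes resp. motifs, groups: cell
    types).  TFs lacking either AUC in a cell type are excluded with a
    warning.  Scores lie in [0, 1]; ties break on TF id.
    """
    g = gene_auc.set_index(["group", "feature"])["auc"]
    m = motif_auc.set_index(["group", "feature"])["auc"]
    celltypes = sorted(set(gene_auc["group"]) & set(motif_auc["group"]))
    rows = []
    for ct in celltypes:
        for motif, tf in sorted(motif_tf.items()):
            if (ct, tf) not in g.index or (ct, motif) not in m.index:
                warnings.warn(f"TF {tf!r}/{motif!r} missing an AUC in {ct!r}; excluded")
                continue
            a_g, a_m = float(g[(ct, tf)]), float(m[(ct, motif)])
            rows.append(
                {"cell_type": ct, "tf": tf, "motif": motif,
                 "auc_gene": a_g, "auc_motif": a_m, "score": a_g * a_m}
            )
    out = pd.DataFrame(rows, columns=["cell_type", "tf", "motif", "auc_gene",
                                      "auc_motif", "score"])
    out = out.sort_values(
        ["cell_type", "score", "tf"], ascending=[True, False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = out.groupby("cell_type").cumcount() + 1
    return out
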