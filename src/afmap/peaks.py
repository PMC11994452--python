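"""Open-chromatin peak annotation against reference interval sets.

Half-open interval overlap, classification of ATAC peaks by ENCODE
candidate cis-regulatory element (cCRE) class, stratification of peaks
by the number of cell types they are called in, and matching of
cell-type peak sets against an external enhancer atlas.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: fixed cCRE vocabulary and tie-break priority (highest first)
CCRE_PRIORITY = ["prom", "enhP", "enhD", "K4m3", "CTCF"]
NOT_ENCODE = "not.Encode"


def overlap_intervals(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """All overlapping pairs between two interval sets (half-open).

    Returns a DataFrame with columns ``a_index, b_index, overlap`` where
    ``overlap`` is the length of the intersection (> 0; touching
    intervals like [0,10) and [10,20) do not overlap).
    """
    rows_a, rows_b, lens = [], [], []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        ai = np.flatnonzero((a["chrom"] == chrom).to_numpy())
        bi = np.flatnonzero((b["chrom"] == chrom).to_numpy())
        b_start = b["start"].to_numpy()[bi]
        b_end = b["end"].to_numpy()[bi]
        order = np.argsort(b_start, kind="mergesort")
        b_start, b_end, bi = b_start[order], b_end[order], bi[order]
        a_start = a["start"].to_numpy()[ai]
        a_end = a["end"].to_numpy()[ai]
        # candidates: b.start < a.end; then require b.end > a.start
        hi = np.searchsorted(b_start, a_end, side="left")
        for k, i in enumerate(ai):
            cand = slice(0, hi[k])
            mask = b_end[cand] > a_start[k]
            js = bi[cand][mask]
            if len(js) == 0:
                continue
            ov = np.minimum(a_end[k], b_end[cand][mask]) - np.maximum(
                a_start[k], b_start[cand][mask]
            )
            rows_a.extend([i] * len(js))
            rows_b.extend(js.tolist())
            lens.extend(ov.tolist())
    return pd.DataFrame(
        {"a_index": rows_a, "b_index": rows_b, "overlap": lens},
        columns=["a_index", "b_index", "overlap"],
    ).astype({"a_index": np.int64, "b_index": np.int64, "overlap": np.int64})


def classify_by_ccre(peaks: pd.DataFrame, ccres: pd.DataFrame) -> pd.Series:
    """Label each peak by its best-overlapping cCRE class.

    The class with the greatest overlap length wins; ties break by the
    fixed priority prom > enhP > enhD > K4m3 > CTCF.  Peaks overlapping
    no cCRE are labeled ``not.Encode``.
    """
    labels = ccres["label"]
    unknown = set(labels) - set(CCRE_PRIORITY)
    if unknown:
        raise ValueError(f"unknown cCRE labels: {sorted(unknown)}")
    prio = {c: r for r, c in enumerate(CCRE_PRIORITY)}
    pairs = overlap_intervals(peaks, ccres)
    out = np.full(len(peaks), NOT_ENCODE, dtype=object)
    if not pairs.empty:
        pairs = pairs.assign(
            label=labels.to_numpy()[pairs["b_index"]],
        )
        pairs["prio"] = pairs["label"].map(prio)
        # best per peak: max overlap, then highest priority (lowest rank)
        pairs = pairs.sort_values(
            ["a_index", "overlap", "prio"], ascending=[True, False, True],
            kind="mergesort",
        )
        best = pairs.drop_duplicates("a_index")
        out[best["a_index"].to_numpy()] = best["label"].to_numpy()
    return pd.Series(out, name="ccre_class")


def specificity_by_celltype_counts(
    per_celltype_calls: dict[str, pd.DataFrame],
    unified_peaks: pd.DataFrame,
    ccre_classes: pd.Series,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count, per unified peak, the cell types whose calls overlap it.

    Returns ``(peak_table, summary)``: the per-peak table has columns
    ``n_celltypes`` and ``ccre_class``; the summary gives, for each
    value of ``n_celltypes``, the fraction of peaks in each cCRE class
    (fractions sum to 1 within each n).
    """
    n_ct = np.zeros(len(unified_peaks), dtype=int)
    for ct in sorted(per_celltype_calls):
        calls = per_celltype_calls[ct]
        if len(calls) == 0:
            warnings.warn(f"cell type {ct!r} has an empty peak call set")
            continue
        pairs = overlap_intervals(unified_peaks, calls)
        hit = np.unique(pairs["a_index"].to_numpy())
        n_ct[hit] += 1
    peak_table = pd.DataFrame(
        {
            "peak_index": np.arange(len(unified_peaks)),
            "n_celltypes": n_ct,
            "ccre_class": ccre_classes.to_numpy(),
        }
    )
    summary = (
        peak_table.groupby(["n_celltypes", "ccre_class"]).size().rename("count").reset_index()
    )
    totals = summary.groupby("n_celltypes")["count"].transform("sum")
    summary["fraction"] = summary["count"] / totals
    return peak_table, summary


def atlas_match_fraction(
    celltype_peaks: dict[str, pd.DataFrame],
    atlas_sets: dict[str, pd.DataFrame],
    threshold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of each cell type's peaks overlapping each atlas set.

    Returns ``(matrix, filtered)``: the full fraction matrix (rows:
    cell types, columns: atlas cell types, NaN for a cell type with no
    peaks) and the long-format pairs that survive the threshold (pairs
    strictly below ``threshold`` removed; a fraction exactly at the
    threshold is kept).
    """
    if not celltype_peaks or not atlas_sets:
        raise ValueError("both peak maps must be non-empty")
    cts = sorted(celltype_peaks)
    ats = sorted(atlas_sets)
    mat = pd.DataFrame(index=cts, columns=ats, dtype=float)
    for ct in cts:
        peaks = celltype_peaks[ct]
        if len(peaks) == 0:
            warnings.warn(f"cell type {ct!r} has zero peaks; fractions undefined")
            continue
        for at in ats:
            pairs = overlap_intervals(peaks, atlas_sets[at])
            n_hit = pairs["a_index"].nunique()
            mat.loc[ct, at] = n_hit / len(peaks)
    long = (
        mat.stack(future_stack=True)
        .rename("fraction")
        .reset_index()
        .rename(columns={"level_0": "cell_type", "level_1": "atlas_cell_type"})
    )
    filtered = long.loc[long["fraction"] >= threshold].reset_index(drop=True)
    return mat, filtered
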