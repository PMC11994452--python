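"""TF motif activity from snATAC counts, and Tn5 footprint profiles.

Motif deviations follow the chromVAR idea: the observed aggregate
accessibility of a motif's peaks in each nucleus is compared with its
expectation under the nucleus's sequencing depth and the peaks' overall
popularity, then bias-corrected and standardized against ``n_bg``
sets of GC- and accessibility-matched background peaks:

    X_im = sum_{p in m} c_ip              (observed)
    E_im = f_i * sum_{p in m} w_p         (expected; f_i = nucleus total,
                                           w_p = peak total / grand total)
    raw_im = (X_im - E_im) / E_im
    z_im  = (raw_im - mean_b dev_ib) / sd_b dev_ib

Background matching uses a joint quantile grid over z-scored GC content
and log mean accessibility rather than chromVAR's Mahalanobis-nearest
sampling - simpler, with the same intent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from afmap.datamodel import MotifPeakMembership, SparseCountMatrix


def peak_bias(
    peak_counts: SparseCountMatrix, peak_gc: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Bias covariates and joint quantile-grid bin per peak.

    Covariates: GC fraction and ln(1 + mean accessibility), each
    z-scored and quantile-binned into ``n_bins``; ``joint_bin`` encodes
    the (gc_bin, access_bin) pair.  With fewer peaks than bins the grid
    collapses with a warning.
    """
    peak_gc = np.asarray(peak_gc, dtype=np.float64)
    if peak_gc.shape[0] != peak_counts.shape[1]:
        raise ValueError("peak_gc length does not match the number of peaks")
    if not np.isfinite(peak_gc).all():
        raise ValueError("non-finite GC content")
    # exact integer column sums so identical peaks are exact ties
    mean_access = (
        np.asarray(peak_counts.matrix.sum(axis=0)).ravel() / peak_counts.shape[0]
    )
    log_access = np.log1p(mean_access)
    n_peaks = len(peak_gc)
    if n_peaks < n_bins:
        warnings.warn(f"fewer peaks ({n_peaks}) than bins ({n_bins}); collapsing grid")
        n_bins = max(1, n_peaks)

    def zscore(x):
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    def qbin(x):
        # midrank-based equal-frequency bins; tied values share a bin
        from scipy.stats import rankdata

        r = rankdata(x, method="average")
        return np.clip(((r - 0.5) * n_bins / len(x)).astype(int), 0, n_bins - 1)

    gc_z, acc_z = zscore(peak_gc), zscore(log_access)
    gc_bin, acc_bin = qbin(gc_z), qbin(acc_z)
    return pd.DataFrame(
        {
            "peak_id": peak_counts.feature_ids,
            "gc": peak_gc,
            "log_mean_access": log_access,
            "gc_z": gc_z,
            "access_z": acc_z,
            "gc_bin": gc_bin,
            "access_bin": acc_bin,
            "joint_bin": gc_bin * n_bins + acc_bin,
            "n_bins": n_bins,
        }
    )


def sample_background_peaks(
    bias: pd.DataFrame, n_bg: int = 50, seed: int = 0
) -> np.ndarray:
    """For each peak, ``n_bg`` bias-matched background peak indices.

    Backgrounds are drawn with replacement, uniformly from the peak's
    joint bin; empty neighborhoods never occur (a peak occupies its own
    bin) but bins with a single member fall back to the nearest
    non-empty bin by grid distance.  Self-sampling is allowed.
    """
    if bias.empty:
        raise ValueError("empty peak set")
    rng = np.random.default_rng(seed)
    n_bins = int(bias["n_bins"].iloc[0])
    gc_bin = bias["gc_bin"].to_numpy()
    acc_bin = bias["access_bin"].to_numpy()
    joint = bias["joint_bin"].to_numpy()
    members: dict[int, np.ndarray] = {
        int(b): np.flatnonzero(joint == b) for b in np.unique(joint)
    }
    bins = np.array(sorted(members))
    bin_gc = bins // n_bins
    bin_acc = bins % n_bins
    out = np.empty((len(bias), n_bg), dtype=int)
    for i in range(len(bias)):
        pool = members[int(joint[i])]
        if len(pool) == 0:  # defensive; cannot happen
            pool = np.arange(len(bias))
        if len(pool) == 1 and len(bias) > 1:
            # nearest non-empty bin by Manhattan grid distance, det. tie-break
            d = np.abs(bin_gc - gc_bin[i]) + np.abs(bin_acc - acc_bin[i])
            d[bins == joint[i]] = np.iinfo(int).max
            near = bins[int(np.argmin(d))]
            pool = np.concatenate([pool, members[int(near)]])
        out[i] = rng.choice(pool, size=n_bg, replace=True)
    return out


@dataclass
class MotifDeviationResult:
    """Per-nucleus motif deviations; rows nuclei, columns motifs."""

    raw: pd.DataFrame
    corrected: pd.DataFrame
    z: pd.DataFrame


def motif_deviations(
    peak_counts: SparseCountMatrix,
    membership: MotifPeakMembership,
    backgrounds: np.ndarray,
    n_bg: int | None = None,
) -> MotifDeviationResult:
    """Bias-corrected motif deviation z-scores per nucleus.

    ``backgrounds`` is the (n_peaks, n_bg) index array from
    :func:`sample_background_peaks`.  Motifs whose background deviations
    have zero spread get missing z-scores (flagged as NaN).
    """
    membership.validate_against(peak_counts.feature_ids)
    motif_ids = membership.motif_ids
    peak_pos = {p: i for i, p in enumerate(peak_counts.feature_ids)}
    counts = peak_counts.matrix.tocsc()
    f = np.asarray(counts.sum(axis=1)).ravel().astype(np.float64)  # nucleus totals
    peak_tot = np.asarray(counts.sum(axis=0)).ravel().astype(np.float64)
    grand = peak_tot.sum()
    if grand == 0:
        raise ValueError("empty peak count matrix")
    w = peak_tot / grand
    if n_bg is None:
        n_bg = backgrounds.shape[1]

    motif_peak_idx = [
        np.array(sorted(peak_pos[p] for p in membership.peaks[m])) for m in motif_ids
    ]

    def deviation(idx_per_motif: list[np.ndarray]) -> np.ndarray:
        rows = np.concatenate(idx_per_motif)
        cols = np.concatenate(
            [np.full(len(ix), j) for j, ix in enumerate(idx_per_motif)]
        )
        M = sp.csc_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(counts.shape[1], len(idx_per_motif)),
        )
        X = np.asarray((counts @ M).todense())
        wsum = np.array([w[ix].sum() for ix in idx_per_motif])
        E = np.outer(f, wsum)
        with np.errstate(divide="ignore", invalid="ignore"):
            dev = (X - E) / E
        return np.where(E > 0, dev, np.nan)

    raw = deviation(motif_peak_idx)
    bg_devs = np.empty((n_bg, *raw.shape))
    for b in range(n_bg):
        bg_idx = [backgrounds[ix, b] for ix in motif_peak_idx]
        bg_devs[b] = deviation(bg_idx)
    bg_mean = bg_devs.mean(axis=0)
    bg_sd = bg_devs.std(axis=0, ddof=1)
    corrected = raw - bg_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        z = corrected / bg_sd
    z = np.where(bg_sd > 0, z, np.nan)
    obs = peak_counts.obs_index()
    return MotifDeviationResult(
        raw=pd.DataFrame(raw, index=obs, columns=motif_ids),
        corrected=pd.DataFrame(corrected, index=obs, columns=motif_ids),
        z=pd.DataFrame(z, index=obs, columns=motif_ids),
    )


def footprint_profile(
    fragments: pd.DataFrame,
    motif_sites: pd.DataFrame,
    groups: dict[str, set[str] | list[str]],
    window: int = 250,
    flank: tuple[int, int] = (200, 250),
) -> pd.DataFrame:
    """Flank-normalized Tn5 insertion profile around motif centers.

    Insertion counts per base offset in ``[-window, +window]`` are
    summed over all sites and all member nuclei of each group, then
    divided by that group's mean count over the flank region
    ``flank[0] <= |offset| <= flank[1]``, so an uninformative profile
    sits at ~1.  Sites on the minus strand are orientation-flipped.
    Groups with no insertions anywhere in the windows get a NaN profile
    and a warning.
    """
    centers = ((motif_sites["start"] + motif_sites["end"]) // 2).to_numpy()
    if "strand" in motif_sites.columns:
        flip = (motif_sites["strand"] == "-").to_numpy()
    else:
        flip = np.zeros(len(centers), dtype=bool)

    barcode_group: dict[str, str] = {}
    for gname, bcs in groups.items():
        for bc in bcs:
            barcode_group[bc] = gname
    frag = fragments.loc[fragments["barcode"].isin(barcode_group)].copy()
    frag["group"] = frag["barcode"].map(barcode_group)
    pos = frag["start"].to_numpy()
    order = np.argsort(pos, kind="mergesort")
    pos_sorted = pos[order]
    group_sorted = frag["group"].to_numpy()[order]

    offsets = np.arange(-window, window + 1)
    counts = {g: np.zeros(2 * window + 1) for g in groups}
    for c, fl in zip(centers, flip):
        lo = np.searchsorted(pos_sorted, c - window, side="left")
        hi = np.searchsorted(pos_sorted, c + window, side="right")
        if lo == hi:
            continue
        d = pos_sorted[lo:hi] - c
        if fl:
            d = -d
        for g in groups:
            sel = d[group_sorted[lo:hi] == g]
            if len(sel):
                counts[g] += np.bincount(sel + window, minlength=2 * window + 1)

    flank_mask = (np.abs(offsets) >= flank[0]) & (np.abs(offsets) <= flank[1])
    profiles = {}
    for g in groups:
        total = counts[g].sum()
        if total == 0:
            warnings.warn(f"group {g!r} has no insertions in any window")
            profiles[g] = np.full(2 * window + 1, np.nan)
            continue
        flank_mean = counts[g][flank_mask].mean()
        profiles[g] = counts[g] / flank_mean if flank_mean > 0 else np.full_like(
            counts[g], np.nan
        )
    return pd.DataFrame(profiles, index=pd.Index(offsets, name="offset"))
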