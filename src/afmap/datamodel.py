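"""Shared in-memory data model for every pipeline stage.

Conventions, fixed once:

* count matrices are observations (rows) x features (columns), stored as
  ``scipy.sparse.csr_matrix`` with non-negative integer values;
* genomic intervals are 0-based, half-open ``[start, end)``;
* tabular results are pandas DataFrames with documented column schemas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("AF", "SR")

#: column order of a differential-expression result table
DE_COLUMNS = ["gene_id", "base_mean", "log2fc", "se", "stat", "p", "fdr"]


class FormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


@dataclass
class SparseCountMatrix:
    """Non-negative integer counts, observations x features.

    Parameters
    ----------
    matrix
        Sparse matrix of shape ``(len(obs_ids), len(feature_ids))``.
    obs_ids
        Unique observation identifiers (nuclei, samples or meta-cells).
    feature_ids
        Unique feature identifiers (genes or peaks).
    """

    matrix: sp.csr_matrix
    obs_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.obs_ids = [str(o) for o in self.obs_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.matrix.shape != (len(self.obs_ids), len(self.feature_ids)):
            raise FormatError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.obs_ids)} obs ids and {len(self.feature_ids)} feature ids"
            )
        if len(set(self.obs_ids)) != len(self.obs_ids):
            raise FormatError("observation ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise FormatError("feature ids are not unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise FormatError("negative count encountered")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def obs_index(self) -> pd.Index:
        return pd.Index(self.obs_ids, name="obs_id")

    def feature_index(self) -> pd.Index:
        return pd.Index(self.feature_ids, name="feature_id")

    def subset_obs(self, keep: np.ndarray | list) -> "SparseCountMatrix":
        """Row subset by boolean mask or integer positions."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SparseCountMatrix(
            self.matrix[keep], [self.obs_ids[i] for i in keep], list(self.feature_ids)
        )

    def subset_features(self, keep: np.ndarray | list) -> "SparseCountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return SparseCountMatrix(
            self.matrix[:, keep], list(self.obs_ids), [self.feature_ids[i] for i in keep]
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.matrix.todense())


def make_nucleus_table(
    nucleus_ids: list[str],
    donor_ids: list[str],
    conditions: list[str],
    cell_types: list[str],
) -> pd.DataFrame:
    """Assemble and validate the per-nucleus metadata table.

    Returns a DataFrame with columns ``nucleus_id, donor_id, condition,
    cell_type``; every nucleus carries all three annotations and
    condition labels come from the fixed {AF, SR} vocabulary.
    """
    df = pd.DataFrame(
        {
            "nucleus_id": nucleus_ids,
            "donor_id": donor_ids,
            "condition": conditions,
            "cell_type": cell_types,
        }
    )
    return validate_nucleus_table(df)


def validate_nucleus_table(df: pd.DataFrame) -> pd.DataFrame:
    required = ["nucleus_id", "donor_id", "condition", "cell_type"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"nucleus table missing columns: {missing}")
    if df["nucleus_id"].duplicated().any():
        raise FormatError("nucleus ids are not unique")
    if df[required].isna().any().any():
        raise FormatError("nucleus table has missing annotations")
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise FormatError(f"unknown condition labels: {sorted(bad)}")
    return df.reset_index(drop=True)


def make_interval_set(
    chrom: list[str],
    start: list[int],
    end: list[int],
    label: list[str] | None = None,
    strand: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble a 0-based half-open genomic interval table.

    Columns ``chrom, start, end`` always present; ``label`` and
    ``strand`` optional (strand "." means unstranded).
    """
    df = pd.DataFrame({"chrom": chrom, "start": start, "end": end})
    if label is not None:
        df["label"] = label
    if strand is not None:
        df["strand"] = strand
    return validate_interval_set(df)


def validate_interval_set(df: pd.DataFrame) -> pd.DataFrame:
    for c in ("chrom", "start", "end"):
        if c not in df.columns:
            raise FormatError(f"interval set missing column {c!r}")
    start = df["start"].to_numpy()
    end = df["end"].to_numpy()
    if (start < 0).any():
        raise FormatError("negative interval coordinate")
    if (start >= end).any():
        i = int(np.flatnonzero(start >= end)[0])
        raise FormatError(f"empty or inverted interval at row {i}: [{start[i]}, {end[i]})")
    if "strand" in df.columns:
        bad = set(df["strand"]) - {"+", "-", "."}
        if bad:
            raise FormatError(f"invalid strand symbols: {sorted(bad)}")
    return df.reset_index(drop=True)


def to_1based_closed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 0-based half-open intervals to 1-based closed coordinates."""
    out = df.copy()
    out["start"] = out["start"] + 1
    return out


def from_1based_closed(df: pd.DataFrame) -> pd.DataFrame:
    """Convert 1-based closed intervals back to 0-based half-open."""
    out = df.copy()
    out["start"] = out["start"] - 1
    return validate_interval_set(out)


@dataclass
class MotifPeakMembership:
    """Binary motif -> peak membership.

    ``peaks[motif_id]`` is the set of peak ids carrying a match for the
    motif; every referenced peak must exist in the peak feature space
    and every motif has at least one peak.
    """

    peaks: dict[str, set[str]]

    def __post_init__(self) -> None:
        for motif, pk in self.peaks.items():
            if not pk:
                raise FormatError(f"motif {motif!r} has no peaks")
            self.peaks[motif] = set(map(str, pk))

    def validate_against(self, peak_ids: list[str]) -> None:
        universe = set(peak_ids)
        for motif, pk in self.peaks.items():
            unknown = pk - universe
            if unknown:
                raise FormatError(
                    f"motif {motif!r} references unknown peaks, e.g. {sorted(unknown)[:3]}"
                )

    @property
    def motif_ids(self) -> list[str]:
        return sorted(self.peaks)

    def indicator(self, peak_ids: list[str]) -> sp.csc_matrix:
        """Peaks x motifs binary indicator in the given peak order."""
        pos = {p: i for i, p in enumerate(peak_ids)}
        rows, cols = [], []
        for j, motif in enumerate(self.motif_ids):
            for p in self.peaks[motif]:
                rows.append(pos[p])
                cols.append(j)
        return sp.csc_matrix(
            (np.ones(len(rows)), (rows, cols)),
            shape=(len(peak_ids), len(self.motif_ids)),
        )


def make_de_table(
    gene_id,
    base_mean,
    log2fc,
    se,
    stat,
    p,
    fdr,
) -> pd.DataFrame:
    """Assemble a per-gene DE result table (one row per tested gene)."""
    df = pd.DataFrame(
        {
            "gene_id": gene_id,
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "stat": stat,
            "p": p,
            "fdr": fdr,
        }
    )
    if df["gene_id"].duplicated().any():
        raise FormatError("duplicate gene in DE table")
    return df


@dataclass
class SignatureSet:
    """Named up/down gene lists plus the thresholds that produced them."""

    name: str
    up_genes: set[str] = field(default_factory=set)
    down_genes: set[str] = field(default_factory=set)
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.up_genes = set(self.up_genes)
        self.down_genes = set(self.down_genes)
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise FormatError(f"genes in both up and down sets: {sorted(overlap)[:3]}")
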