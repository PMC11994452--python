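"""Readers and writers for the on-disk artifact formats.

Formats: Matrix Market triples (``matrix.mtx`` + ``features.tsv`` +
``barcodes.tsv``, genes-in-rows on disk as in the 10x convention,
transposed to obs x features at this boundary), BED (0-based half-open,
tab separated), TSV result tables with ``NA`` for missing values, and a
BED-like fragments file (chrom, start, end, barcode).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from afmap.datamodel import FormatError, SparseCountMatrix, validate_interval_set

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"


def write_matrix_triple(counts: SparseCountMatrix, dir_path: str | os.PathLike) -> None:
    """Write a count matrix as an MTX triple (features in MTX rows)."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    # disk convention: features x observations
    scipy.io.mmwrite(str(d / MATRIX_FILE), sp.coo_matrix(counts.matrix.T), field="integer")
    pd.Series(counts.feature_ids).to_csv(d / FEATURES_FILE, sep="\t", index=False, header=False)
    pd.Series(counts.obs_ids).to_csv(d / BARCODES_FILE, sep="\t", index=False, header=False)


def read_matrix_triple(dir_path: str | os.PathLike) -> SparseCountMatrix:
    """Read an MTX triple; integer values preserved exactly.

    Raises
    ------
    FormatError
        If the MTX dimensions disagree with the feature/barcode files.
    """
    d = Path(dir_path)
    mat = sp.csr_matrix(scipy.io.mmread(str(d / MATRIX_FILE)))
    features = _read_id_column(d / FEATURES_FILE)
    barcodes = _read_id_column(d / BARCODES_FILE)
    n_feat, n_obs = mat.shape
    if n_feat != len(features) or n_obs != len(barcodes):
        raise FormatError(
            f"MTX declares {n_feat} features x {n_obs} barcodes but id files "
            f"have {len(features)} and {len(barcodes)} rows"
        )
    out = mat.T.tocsr()
    out.data = np.rint(out.data).astype(np.int64)
    return SparseCountMatrix(out, barcodes, features)


def _read_id_column(path: Path) -> list[str]:
    if path.stat().st_size == 0:
        return []
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str)[0]
    return ids.tolist()


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Parse a 3-6 column BED file into an interval table.

    Column 4 becomes ``label``, column 6 ``strand``; the score column is
    discarded.  Coordinates are kept 0-based half-open.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative start {start}")
            if start >= end:
                raise FormatError(f"{path}:{lineno}: empty interval [{start}, {end})")
            rec = {"chrom": chrom, "start": start, "end": end}
            if len(parts) >= 4:
                rec["label"] = parts[3]
            if len(parts) >= 6:
                rec["strand"] = parts[5]
            rows.append(rec)
    cols = ["chrom", "start", "end"]
    if rows and "label" in rows[0]:
        cols.append("label")
    if rows and "strand" in rows[0]:
        cols.append("strand")
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        df = pd.DataFrame(columns=["chrom", "start", "end"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    return validate_interval_set(df)


def write_bed(intervals: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an interval table as BED (score column filled with 0)."""
    df = validate_interval_set(intervals)
    cols = [df["chrom"], df["start"], df["end"]]
    if "strand" in df.columns:
        cols.append(df.get("label", pd.Series(["."] * len(df))))
        cols.append(pd.Series([0] * len(df)))
        cols.append(df["strand"])
    elif "label" in df.columns:
        cols.append(df["label"])
    out = pd.concat(cols, axis=1)
    out.to_csv(path, sep="\t", index=False, header=False)


def write_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a result table as TSV: header row, ``NA`` for missing,
    full float precision (repr round-trip)."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=None)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


def write_fragments(fragments: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a fragments file: chrom, start, end, barcode (no header)."""
    fragments[["chrom", "start", "end", "barcode"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_fragments(path: str | os.PathLike) -> pd.DataFrame:
    if Path(path).stat().st_size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "barcode"]).astype(
            {"start": np.int64, "end": np.int64}
        )
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "barcode"]
    )


def write_signature(sig, path: str | os.PathLike) -> None:
    """Serialize a SignatureSet: threshold provenance header + two columns."""
    with open(path, "w") as fh:
        fh.write(f"# signature: {sig.name}\n")
        for k in sorted(sig.thresholds):
            fh.write(f"# {k}: {sig.thresholds[k]}\n")
        fh.write("gene\tdirection\n")
        for g in sorted(sig.up_genes):
            fh.write(f"{g}\tup\n")
        for g in sorted(sig.down_genes):
            fh.write(f"{g}\tdown\n")


def read_signature(path: str | os.PathLike):
    from afmap.datamodel import SignatureSet

    name = "signature"
    thresholds: dict = {}
    up, down = set(), set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# signature:"):
                name = line.split(":", 1)[1].strip()
            elif line.startswith("#"):
                k, v = line[1:].split(":", 1)
                try:
                    thresholds[k.strip()] = float(v)
                except ValueError:
                    thresholds[k.strip()] = v.strip()
            elif line and line != "gene\tdirection":
                g, direction = line.split("\t")
                (up if direction == "up" else down).add(g)
    return SignatureSet(name=name, up_genes=up, down_genes=down, thresholds=thresholds)
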