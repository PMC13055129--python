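"""Interchange formats: 10x-style MTX triplets and copy-number segment tables.

All genomic coordinates in files are 1-based closed.  The MTX triplet follows
the 10x convention of a features x barcodes MatrixMarket coordinate matrix
with features.tsv / barcodes.tsv alongside; in memory the package works with
cells x genes matrices, so the matrix is transposed on read and write.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "write_counts_10x",
    "read_counts_10x",
    "write_segments",
    "read_segments",
]

SEGMENT_COLUMNS = ["chromosome", "start", "end", "copy_number"]


def write_counts_10x(out_dir, counts, genes: pd.DataFrame, barcodes) -> None:
    """Write matrix.mtx (features x barcodes, integer), features.tsv, barcodes.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat = sp.coo_matrix(counts).T.astype(np.int64)
    scipy.io.mmwrite(str(out / "matrix.mtx"), mat, field="integer")
    genes.to_csv(out / "features.tsv", sep="\t", index=False)
    pd.Series(list(barcodes), name="cell_id").to_csv(out / "barcodes.tsv", sep="\t", index=False)


def _check_mtx_nnz(path: Path) -> None:
    """Verify the MatrixMarket header's nnz against the number of data lines."""
    with open(path) as fh:
        header = None
        n_data = 0
        for line in fh:
            if line.startswith("%") or not line.strip():
                continue
            if header is None:
                header = line.split()
            else:
                n_data += 1
    if header is None or len(header) != 3:
        raise ValueError(f"malformed MatrixMarket size line in {path}")
    declared = int(header[2])
    if declared != n_data:
        raise ValueError(
            f"{path}: header declares {declared} entries but file holds {n_data}"
        )


def read_counts_10x(in_dir):
    """Read a 10x-style triplet; returns (cells x genes csr, genes df, barcodes list)."""
    d = Path(in_dir)
    for fname in ("matrix.mtx", "features.tsv", "barcodes.tsv"):
        if not (d / fname).exists():
            raise FileNotFoundError(f"missing {fname} in {d}")
    _check_mtx_nnz(d / "matrix.mtx")
    mat = scipy.io.mmread(str(d / "matrix.mtx"))
    if not np.issubdtype(mat.dtype, np.integer):
        if not np.allclose(mat.data, np.round(mat.data)):
            raise ValueError("matrix.mtx holds non-integer entries")
        mat = mat.astype(np.int64)
    counts = sp.csr_matrix(mat.T)
    genes = pd.read_csv(d / "features.tsv", sep="\t")
    barcodes = pd.read_csv(d / "barcodes.tsv", sep="\t")["cell_id"].tolist()
    if counts.shape != (len(barcodes), len(genes)):
        raise ValueError(
            f"matrix is {counts.shape} but metadata describes "
            f"({len(barcodes)} cells, {len(genes)} genes)"
        )
    return counts, genes, barcodes


def write_segments(path, segments: pd.DataFrame) -> None:
    cols = [c for c in segments.columns if c in SEGMENT_COLUMNS or c == "group"]
    segments[cols].to_csv(path, sep="\t", index=False)


def read_segments(path, chrom_names=None) -> pd.DataFrame:
    """Read and validate a segment table (tab-separated, 1-based closed).

    Rows are sorted by (chromosome, start); overlapping same-chromosome rows
    raise with their row numbers.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (df["start"] > df["end"]).any():
        bad = df.index[df["start"] > df["end"]].tolist()
        raise ValueError(f"{path}: start > end at rows {bad}")
    if (df["copy_number"] < 0).any():
        raise ValueError(f"{path}: negative copy numbers")
    if chrom_names is not None:
        unknown = set(df["chromosome"]) - set(chrom_names)
        if unknown:
            raise ValueError(f"{path}: unknown chromosomes {sorted(unknown)}")
    df = df.sort_values(["chromosome", "start"], kind="stable").reset_index(drop=True)
    for chrom, sub in df.groupby("chromosome", sort=False):
        ends = sub["end"].to_numpy()
        starts = sub["start"].to_numpy()
        bad = np.flatnonzero(starts[1:] <= ends[:-1])
        if bad.size:
            rows = sub.index[bad + 1].tolist()
            raise ValueError(f"{path}: overlapping segments on {chrom} at rows {rows}")
    return df
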