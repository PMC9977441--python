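"""Readers and writers for the plain-text formats used by the pipeline.

Conventions: BED is 0-based half-open; SEG is 1-based inclusive on disk and
converted to 0-based half-open on read.  Matrices are TSV with loci as rows
and samples as columns.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import GenomeModel

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "n_bins", "seg_mean"]


class FormatError(ValueError):
    """Malformed input file; message carries the offending row number."""


def write_seg(segments: pd.DataFrame, path) -> None:
    """Write a segment table as SEG (1-based inclusive coordinates).

    Extra columns beyond the canonical six (e.g. a ``state`` column on
    called segments) are preserved.
    """
    out = segments.copy()
    out["start"] = out["start"].astype(np.int64) + 1
    out["end"] = out["end"].astype(np.int64)
    cols = SEG_COLUMNS + [c for c in out.columns if c not in SEG_COLUMNS]
    out[cols].to_csv(path, sep="\t", index=False)


def read_seg(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SEG file {path} lacks columns {missing}")
    df["start"] = df["start"].astype(np.int64) - 1
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise FormatError(f"SEG row {bad[0] + 2}: end <= start")
    if not np.isfinite(df["seg_mean"]).all():
        row = int(df.index[~np.isfinite(df["seg_mean"])][0]) + 2
        raise FormatError(f"SEG row {row}: non-finite seg_mean")
    return df


def write_bed(loci: pd.DataFrame, path) -> None:
    """Write loci as BED4 (chrom, start, end, name), 0-based half-open."""
    loci[["chrom", "start", "end", "locus_id"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "locus_id"],
        dtype={"chrom": str, "locus_id": str},
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise FormatError(f"BED row {bad[0] + 1}: end <= start")
    return df


def write_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="locus_id")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("bcr_event", "met_event"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_genome(genome: GenomeModel, path) -> None:
    pd.DataFrame(
        {"chrom": genome.chrom_names, "length": genome.chrom_lengths}
    ).to_csv(path, sep="\t", index=False)


def read_genome(path) -> GenomeModel:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return GenomeModel(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))
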