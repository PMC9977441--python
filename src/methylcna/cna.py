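"""Bin-level copy ratio processing: reference normalization, change-point
segmentation, and gene/locus-level summarization.

A *bin track* is a DataFrame with columns ``sample_id, chrom, start, end,
log2_ratio`` holding sorted, non-overlapping bins per chromosome.  A
*segment table* has columns ``sample_id, chrom, start, end, n_bins,
seg_mean``.  Locus matrices are DataFrames with loci as rows and samples as
columns (log2 units); loci with no overlapping territory are NaN.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

BIN_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]


def normalize_to_reference(
    tumor_bins: pd.DataFrame, reference_bins: pd.DataFrame
) -> pd.DataFrame:
    """log2(tumor / pooled-reference) per bin, median-centered per sample.

    ``tumor_bins`` carries per-sample raw intensities in a ``value`` column;
    ``reference_bins`` carries the per-bin mean intensity over the pooled
    normal cohort (columns ``chrom, start, end, value``).  Bin grids must be
    identical.
    """
    ref = reference_bins.reset_index(drop=True)
    if not np.isfinite(ref["value"]).all() or (ref["value"] <= 0).any():
        raise ValueError("reference bin values must be finite and positive")
    out = []
    for sample_id, grp in tumor_bins.groupby("sample_id", sort=False):
        grp = grp.reset_index(drop=True)
        if len(grp) != len(ref) or not (
            (grp["chrom"].values == ref["chrom"].values).all()
            and (grp["start"].values == ref["start"].values).all()
            and (grp["end"].values == ref["end"].values).all()
        ):
            raise ValueError(f"bin grid of sample {sample_id!r} does not match reference")
        ratio = np.log2(grp["value"].values / ref["value"].values)
        ratio = ratio - np.median(ratio)
        out.append(
            pd.DataFrame(
                {
                    "sample_id": sample_id,
                    "chrom": grp["chrom"].values,
                    "start": grp["start"].values,
                    "end": grp["end"].values,
                    "log2_ratio": ratio,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def _split_stats(x: np.ndarray, min_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean-shift t-like statistic for every split point k (left = x[:k]).

    The scale is a robust per-segment noise estimate from first differences
    (MAD), so the statistic localizes change-points without being pulled by
    the mean shift itself.
    """
    n = len(x)
    ks = np.arange(min_bins, n - min_bins + 1)
    csum = np.cumsum(x)
    n1 = ks.astype(float)
    n2 = n - n1
    m1 = csum[ks - 1] / n1
    m2 = (csum[-1] - csum[ks - 1]) / n2
    diff = m2 - m1
    d = np.diff(x)
    sigma = 1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0)
    scale = np.sqrt(n1 * n2 / n)
    # zero-noise floor: a genuine mean difference must dominate any split,
    # but cumsum round-off on constant data must not count as a difference
    atol = 1e-10 * (np.abs(x).max() + 1.0)
    t = np.where(np.abs(diff) > atol, diff * scale / max(sigma, atol), 0.0)
    return ks, t


def _split_chromosome(x: np.ndarray, lo: int, hi: int, min_bins: int, alpha: float,
                      breaks: list[int]) -> None:
    seg = x[lo:hi]
    n = len(seg)
    if n < 2 * min_bins:
        return
    ks, t = _split_stats(seg, min_bins)
    i = int(np.argmax(np.abs(t)))
    tmax = abs(t[i])
    # normal-theory p-value with a Sidak guard for the number of candidate
    # splits scanned; keeps constant noisy tracks from fragmenting
    p_single = 2.0 * stats.norm.sf(tmax)
    p_adj = 1.0 - (1.0 - min(p_single, 1.0)) ** len(ks)
    if p_adj < alpha:
        k = lo + int(ks[i])
        breaks.append(k)
        _split_chromosome(x, lo, k, min_bins, alpha, breaks)
        _split_chromosome(x, k, hi, min_bins, alpha, breaks)


def segment_bins(track: pd.DataFrame, min_bins: int = 5, alpha: float = 0.01) -> pd.DataFrame:
    """Recursive binary segmentation of a bin track.

    Each chromosome is split at the maximal mean-shift statistic; a split is
    accepted when its (scan-adjusted) normal-theory p-value is below
    ``alpha`` and both sides retain at least ``min_bins`` bins.  A
    chromosome with fewer than ``min_bins`` bins yields a single segment.
    """
    if min_bins < 2:
        raise ValueError("min_bins must be >= 2")
    rows = []
    for (sample_id, chrom), grp in track.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        x = grp["log2_ratio"].to_numpy(float)
        breaks: list[int] = []
        _split_chromosome(x, 0, len(x), min_bins, alpha, breaks)
        bounds = [0] + sorted(breaks) + [len(x)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            rows.append(
                (
                    sample_id,
                    chrom,
                    int(grp["start"].iloc[a]),
                    int(grp["end"].iloc[b - 1]),
                    b - a,
                    float(np.mean(x[a:b])),
                )
            )
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "start", "end", "n_bins", "seg_mean"])


def summarize_loci(segments: pd.DataFrame, annotation: pd.DataFrame,
                   value_col: str = "seg_mean") -> pd.DataFrame:
    """Locus-level matrix: length-weighted mean of overlapping segment means.

    ``annotation`` is a BED-like frame (``chrom, start, end, locus_id``,
    0-based half-open).  Returns a loci x samples DataFrame; a locus with no
    overlapping segment territory in a sample is NaN.
    """
    ann = annotation.reset_index(drop=True)
    if ann["locus_id"].duplicated().any():
        raise ValueError("duplicate locus_id in annotation")
    sample_ids = list(dict.fromkeys(segments["sample_id"]))
    values = pd.DataFrame(
        np.nan, index=ann["locus_id"].tolist(), columns=sample_ids, dtype=float
    )
    seg_chroms = set(segments["chrom"])
    for chrom, loci in ann.groupby("chrom", sort=False):
        if chrom not in seg_chroms:
            raise ValueError(f"annotation chromosome {chrom!r} has no segments")
    for (sample_id, chrom), grp in segments.groupby(["sample_id", "chrom"], sort=False):
        loci = ann[ann["chrom"] == chrom]
        if loci.empty:
            continue
        grp = grp.sort_values("start")
        s_start = grp["start"].to_numpy(np.int64)
        s_end = grp["end"].to_numpy(np.int64)
        s_mean = grp[value_col].to_numpy(float)
        l_start = loci["start"].to_numpy(np.int64)
        l_end = loci["end"].to_numpy(np.int64)
        # overlapping segment index range per locus
        i0 = np.searchsorted(s_end, l_start, side="right")
        i1 = np.searchsorted(s_start, l_end, side="left")
        vals = np.full(len(loci), np.nan)
        single = i1 - i0 == 1
        vals[single] = s_mean[i0[single]]
        for j in np.nonzero(i1 - i0 > 1)[0]:
            sl = slice(i0[j], i1[j])
            w = np.minimum(s_end[sl], l_end[j]) - np.maximum(s_start[sl], l_start[j])
            w = np.clip(w, 0, None).astype(float)
            if w.sum() > 0:
                vals[j] = float(np.dot(w, s_mean[sl]) / w.sum())
        values.loc[loci["locus_id"].tolist(), sample_id] = vals
    return values


def prepare_matrix(matrix: pd.DataFrame, max_missing_frac: float = 0.10) -> pd.DataFrame:
    """Screen-ready matrix: drop loci missing in more than
    ``max_missing_frac`` of samples, mean-impute the rest per locus."""
    frac = matrix.isna().mean(axis=1)
    kept = matrix.loc[frac <= max_missing_frac]
    means = kept.mean(axis=1)
    return kept.T.fillna(means).T
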