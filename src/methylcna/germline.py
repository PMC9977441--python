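"""Germline CNV identification from a normal-tissue cohort and subtraction
from tumor hit lists.

Copy number differences between ancestry groups observed in *normal*
tissue cannot be somatic; loci significant in the normal-tissue screen are
treated as germline copy number variation (gCNV) and removed from tumor
sCNA lists.  Loci are matched between cohorts by locus id on a shared
annotation, not by coordinate overlap.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .association import screen_group


@dataclass(frozen=True)
class LocusSet:
    """A set of locus ids with its provenance and the FDR used to derive it."""

    ids: frozenset[str]
    provenance: str = ""
    fdr: float | None = None

    def __len__(self) -> int:
        return len(self.ids)


def derive_germline_set(
    normal_matrix: pd.DataFrame,
    normal_clinical: pd.DataFrame,
    fdr: float = 0.001,
    covariates=(),
    moderate: bool = True,
) -> LocusSet:
    """Loci whose copy number differs between groups in normal tissue.

    Runs the group screen on the normal-tissue matrix (group-only design by
    default: normal-tissue donors lack PSA/grade) and keeps loci at
    ``q < fdr``.
    """
    if fdr <= 0:
        return LocusSet(frozenset(), provenance="normal_germline", fdr=fdr)
    res = screen_group(normal_matrix, normal_clinical, covariates=covariates,
                       moderate=moderate)
    hits = frozenset(res.index[res["q"] < fdr])
    return LocusSet(hits, provenance="normal_germline", fdr=fdr)


def filter_germline(tumor_hits: LocusSet, germline: LocusSet):
    """Subtract germline loci from a tumor hit list.

    Returns ``(retained, removed, summary)`` where ``summary`` reports the
    input size, counts removed/retained, and the removed percentage rounded
    to the nearest integer.
    """
    removed_ids = tumor_hits.ids & germline.ids
    retained_ids = tumor_hits.ids - germline.ids
    n = len(tumor_hits.ids)
    summary = {
        "n_hits": n,
        "n_removed": len(removed_ids),
        "n_retained": len(retained_ids),
        "pct_removed": int(round(100.0 * len(removed_ids) / n)) if n else 0,
    }
    retained = LocusSet(retained_ids, provenance=f"{tumor_hits.provenance}_filtered",
                        fdr=tumor_hits.fdr)
    removed = LocusSet(removed_ids, provenance=f"{tumor_hits.provenance}_germline",
                       fdr=tumor_hits.fdr)
    return retained, removed, summary


def overlap_sets(a: LocusSet, b: LocusSet) -> tuple[int, int]:
    """Size of ``a & b`` and the percentage of ``a`` contained in ``b``
    (rounded to the nearest integer)."""
    inter = len(a.ids & b.ids)
    pct = int(round(100.0 * inter / len(a.ids))) if len(a.ids) else 0
    return inter, pct
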