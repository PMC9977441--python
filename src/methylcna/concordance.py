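"""Cross-platform agreement utilities: per-locus correlations between two
copy number matrices and correspondence-at-the-top (CAT) curves."""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .association import bh_adjust


def per_locus_correlation(a: pd.DataFrame, b: pd.DataFrame,
                          q_threshold: float = 0.05):
    """Locus-wise Spearman correlation across shared samples.

    Returns ``(table, summary)``: a per-locus frame of rho/p/q and a
    summary dict with the count and fraction of loci at ``q <
    q_threshold`` with positive rho.
    """
    loci = a.index.intersection(b.index)
    samples = a.columns.intersection(b.columns)
    if len(samples) < 3:
        raise ValueError("need at least 3 shared samples")
    rows = []
    for locus in loci:
        rho, p = stats.spearmanr(a.loc[locus, samples], b.loc[locus, samples])
        rows.append((float(rho), float(p)))
    tab = pd.DataFrame(rows, columns=["rho", "p"], index=loci)
    tab["p"] = tab["p"].fillna(1.0)
    tab["q"] = bh_adjust(tab["p"].to_numpy())
    hit = (tab["q"] < q_threshold) & (tab["rho"] > 0)
    summary = {
        "n_loci": len(loci),
        "n_significant_positive": int(hit.sum()),
        "pct_significant_positive": int(round(100.0 * hit.mean())) if len(loci) else 0,
    }
    return tab, summary


def _ranks(scores: pd.Series, absolute: bool) -> pd.Series:
    s = scores.abs() if absolute else scores
    # descending by score; ties broken by locus id for determinism
    order = sorted(s.index, key=lambda i: (-s[i], i))
    return pd.Series(np.arange(len(order)), index=order)


def cat_curve(scores_a: pd.Series, scores_b: pd.Series,
              absolute: bool = True) -> pd.DataFrame:
    """Correspondence-at-the-top curve for two rankings of one universe.

    ``concordance(k)`` is the fraction of the top-k loci (ranked by
    descending absolute value by default) shared between the two lists.
    """
    if set(scores_a.index) != set(scores_b.index):
        raise ValueError("score lists must rank the same locus universe")
    ra = _ranks(scores_a, absolute)
    rb = _ranks(scores_b, absolute).reindex(ra.index)
    worst = np.maximum(ra.to_numpy(), rb.to_numpy())
    worst.sort()
    k = np.arange(1, len(ra) + 1)
    # a locus is in both top-k lists iff max(rank_a, rank_b) < k
    shared = np.searchsorted(worst, k, side="left")
    return pd.DataFrame({"k": k, "concordance": shared / k})
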