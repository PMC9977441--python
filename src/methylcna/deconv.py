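"""Reference-based cell-type deconvolution of methylation beta values and
correlation of immune fractions with PGA.

Each sample's beta vector over signature CpGs is modeled as a convex
combination of reference cell-type profiles; fractions are estimated by
constrained least squares (non-negative, summing to one), solved as a
non-negative least-squares problem with the sum-to-one constraint imposed
through a heavily weighted augmentation row.  This is a deterministic
stand-in for SVM-based deconvolution with the same input/output contract.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

_SUM_WEIGHT = 1e4


@dataclass
class DeconvResult:
    fractions: pd.DataFrame  # samples x cell types, each row sums to 1
    residuals: pd.Series     # per-sample residual norm of the fit


def deconvolve(betas: pd.DataFrame, signature: pd.DataFrame) -> DeconvResult:
    """Estimate cell-type fractions per sample.

    ``betas``: CpGs x samples; ``signature``: CpGs x cell types (reference
    beta profiles).  Only shared CpG ids are used; at least twice as many
    shared CpGs as cell types are required.
    """
    shared = betas.index.intersection(signature.index)
    k = signature.shape[1]
    if len(shared) < 2 * k:
        raise ValueError(
            f"only {len(shared)} shared CpGs for {k} cell types; need >= {2 * k}"
        )
    S = signature.loc[shared].to_numpy(float)
    if np.linalg.matrix_rank(S) < k:
        raise ValueError("signature matrix is rank-deficient")
    B = betas.loc[shared].to_numpy(float)
    A = np.vstack([S, _SUM_WEIGHT * np.ones((1, k))])
    fracs = np.empty((betas.shape[1], k))
    resid = np.empty(betas.shape[1])
    for j in range(betas.shape[1]):
        b = np.append(B[:, j], _SUM_WEIGHT)
        f, _ = nnls(A, b)
        total = f.sum()
        if total <= 0:
            raise ValueError("degenerate fit: all-zero fractions")
        f /= total
        fracs[j] = f
        resid[j] = float(np.linalg.norm(S @ f - B[:, j]))
    fr = pd.DataFrame(fracs, index=betas.columns, columns=signature.columns)
    return DeconvResult(fractions=fr, residuals=pd.Series(resid, index=betas.columns))


def correlate_with_pga(
    fractions: pd.DataFrame,
    pga: pd.DataFrame,
    cell_type: str = "Treg",
    clinical: pd.DataFrame | None = None,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman correlation of a cell-type fraction with pga_total.

    Samples flagged ``excluded`` (no altered segments) are dropped.  If
    ``clinical`` is given, per-group strata are reported alongside the
    overall correlation.  Returns a frame of (stratum, rho, p, n).
    """
    pga_idx = pga.set_index("sample_id")
    shared = fractions.index.intersection(pga_idx.index)
    pga_idx = pga_idx.loc[shared]
    keep = shared[~pga_idx["excluded"].to_numpy(bool)]
    frac = fractions.loc[keep, cell_type]
    pvals = pga_idx.loc[keep, "pga_total"]
    strata = {"overall": keep}
    if clinical is not None:
        grp = clinical.set_index("sample_id")["group"]
        for level in sorted(grp.unique()):
            strata[str(level)] = keep[grp.reindex(keep) == level]
    rows = []
    for name, idx in strata.items():
        if len(idx) < min_n:
            raise ValueError(f"stratum {name!r} has fewer than {min_n} usable samples")
        x, y = frac.loc[idx].to_numpy(), pvals.loc[idx].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"stratum {name!r}: correlation undefined for constant input")
        rho, p = stats.spearmanr(x, y)
        rows.append((name, float(rho), float(p), len(idx)))
    return pd.DataFrame(rows, columns=["stratum", "rho", "p", "n"])
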