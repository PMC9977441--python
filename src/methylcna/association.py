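"""Genome-wide per-locus linear-model screens with BH FDR.

Each locus's continuous copy number is regressed on a predictor of
interest (two-level group label, or continuous ancestry fraction) plus
clinical covariates: age, preoperative PSA, and Gleason grade entered as a
binary low (GG1-2) vs high (GG3-5) indicator.  The per-locus fits share
one design matrix, so the whole screen is a single least-squares solve.

Group screens optionally apply empirical-Bayes variance moderation:
per-locus residual variances are shrunk toward a pooled prior estimated by
method of moments from the scaled-F marginal of the sample variances, and
t statistics use the augmented degrees of freedom.  Ancestry screens
default to plain per-locus least squares.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

COVARIATES = ("age", "psa", "grade")


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def grade_binary(grade_group: pd.Series) -> np.ndarray:
    """Low (GG1-2) vs high (GG3-5) risk indicator."""
    gg = np.asarray(grade_group, int)
    if ((gg < 1) | (gg > 5)).any():
        raise ValueError("grade_group must be in 1..5")
    return (gg >= 3).astype(float)


def _design(clinical: pd.DataFrame, predictor: str, covariates, log_psa: bool):
    cols = [np.ones(len(clinical))]
    if predictor == "group":
        levels = sorted(clinical["group"].unique())
        if len(levels) != 2:
            raise ValueError("group predictor requires exactly two levels")
        x = (clinical["group"] == levels[1]).to_numpy(float)
        if x.sum() < 2 or (1 - x).sum() < 2:
            raise ValueError("need at least 2 samples per group")
    elif predictor == "ancestry":
        x = clinical["ancestry_fraction"].to_numpy(float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    cols.append(x)
    names = ["intercept", predictor]
    for cov in covariates:
        if cov == "grade":
            cols.append(grade_binary(clinical["grade_group"]))
        elif cov == "psa":
            v = clinical["psa"].to_numpy(float)
            cols.append(np.log(v) if log_psa else v)
        else:
            cols.append(clinical[cov].to_numpy(float))
        names.append(cov)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("fewer samples than model parameters")
    return X, names


def _trigamma_inverse(y: float) -> float:
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        delta = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += delta
        if abs(delta) < 1e-10 * x:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink residual variances toward a pooled prior (empirical Bayes).

    Moments of ``log(s2)`` identify the prior degrees of freedom ``d0`` and
    scale ``s0^2`` of a scaled inverse-chi-square prior; returns the
    posterior variances ``(d0*s0^2 + df*s2) / (d0 + df)`` and ``d0``.
    """
    s2 = np.maximum(np.asarray(s2, float), 1e-300)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    ev = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if ev <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(np.mean(e)))
        return np.full_like(s2, s0_2), d0
    d0 = 2.0 * _trigamma_inverse(ev)
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return (d0 * s0_2 + df * s2) / (d0 + df), d0


def _screen(matrix: pd.DataFrame, clinical: pd.DataFrame, predictor: str,
            covariates, moderate: bool, log_psa: bool) -> pd.DataFrame:
    clin = clinical.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    X, names = _design(clin, predictor, covariates, log_psa)
    Y = matrix.to_numpy(float).T  # samples x loci
    if np.isnan(Y).any():
        raise ValueError("matrix contains missing values; run prepare_matrix first")
    n, p = X.shape
    coef, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    df_resid = n - p
    s2 = (resid ** 2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    j = names.index(predictor)
    cj = xtx_inv[j, j]
    if moderate:
        s2_post, d0 = moderate_variances(s2, df_resid)
        df_t = df_resid + d0
    else:
        s2_post, df_t = s2, df_resid
    se = np.sqrt(s2_post * cj)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef[j] / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df_t)
    pval = np.clip(np.nan_to_num(pval, nan=1.0), 0.0, 1.0)
    return pd.DataFrame(
        {
            "estimate": coef[j],
            "se": se,
            "statistic": tstat,
            "p": pval,
            "q": bh_adjust(pval),
        },
        index=matrix.index,
    )


def screen_group(matrix: pd.DataFrame, clinical: pd.DataFrame,
                 covariates=COVARIATES, moderate: bool = True,
                 log_psa: bool = False) -> pd.DataFrame:
    """Per-locus copy number ~ group + covariates, moderated t by default."""
    return _screen(matrix, clinical, "group", covariates, moderate, log_psa)


def screen_ancestry(matrix: pd.DataFrame, clinical: pd.DataFrame,
                    covariates=COVARIATES, moderate: bool = False,
                    log_psa: bool = False) -> pd.DataFrame:
    """Per-locus copy number ~ ancestry_fraction + covariates (plain GLM)."""
    if clinical["ancestry_fraction"].nunique() < 2:
        raise ValueError("ancestry_fraction is constant; predictor is degenerate")
    return _screen(matrix, clinical, "ancestry", covariates, moderate, log_psa)
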