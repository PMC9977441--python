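"""Per-locus Cox proportional-hazards screens and Kaplan-Meier / log-rank
analyses of categorical gain calls.

The screen fits, for every locus, a multivariable Cox model of a censored
outcome (biochemical recurrence or metastasis) on the locus's continuous
log2 copy number adjusted for ancestry fraction, age, PSA and binary
grade.  The partial likelihood uses Efron's tie correction and is
maximized by Newton-Raphson with step-halving; the screen never aborts on
a single locus — non-convergent or degenerate loci yield NaN rows.  BH
adjustment runs across the loci that produced a p-value.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .association import bh_adjust, grade_binary

COX_COVARIATES = ("ancestry_fraction", "age", "psa", "grade")


class CoxError(ValueError):
    pass


def _efron_loglik_grad_hess(beta, times, events, X):
    """Efron partial log-likelihood with gradient and Hessian.

    Rows must be sorted by ascending time.  Risk-set aggregates are built
    by suffix sums; tie groups contribute the Efron-averaged denominators.
    """
    n, p = X.shape
    eta = X @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums over the risk set {i: t_i >= t}
    S = np.cumsum(w[::-1])[::-1]
    Z = np.cumsum(wx[::-1], axis=0)[::-1]
    Q = np.cumsum(wxx[::-1], axis=0)[::-1]
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        dead = np.nonzero(events[i:j])[0] + i
        d = len(dead)
        if d:
            s_r, z_r, q_r = S[i], Z[i], Q[i]
            s_d = w[dead].sum()
            z_d = wx[dead].sum(axis=0)
            q_d = wxx[dead].sum(axis=0)
            ll += eta[dead].sum()
            grad += X[dead].sum(axis=0)
            for l in range(d):
                f = l / d
                phi = s_r - f * s_d
                v = (z_r - f * z_d) / phi
                ll -= np.log(phi)
                grad -= v
                hess -= (q_r - f * q_d) / phi - np.outer(v, v)
        i = j
    return ll, grad, hess


def cox_fit(times, events, X, tol: float = 1e-8, max_iter: int = 50):
    """Maximize the Efron partial likelihood by Newton-Raphson.

    Returns ``(beta, se, converged)``; ``se`` comes from the inverse
    observed information.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    X = np.asarray(X, float)
    order = np.argsort(times, kind="stable")
    times, events, X = times[order], events[order], X[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _efron_loglik_grad_hess(beta, times, events, X)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            raise CoxError("singular information matrix")
        new_beta = beta - step
        new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, times, events, X)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll) and halvings < 20:
            step /= 2.0
            new_beta = beta - step
            new_ll, new_grad, new_hess = _efron_loglik_grad_hess(new_beta, times, events, X)
            halvings += 1
        if not np.isfinite(new_ll):
            raise CoxError("partial likelihood diverged")
        delta = abs(new_ll - ll)
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if delta <= tol * (abs(ll) + 1e-12):
            converged = True
            break
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return beta, se, converged


def _outcome_columns(outcome: str) -> tuple[str, str]:
    if outcome == "bcr":
        return "bcr_time", "bcr_event"
    if outcome in ("met", "metastasis"):
        return "met_time", "met_event"
    raise ValueError(f"unknown outcome {outcome!r}")


def cox_screen(matrix: pd.DataFrame, clinical: pd.DataFrame, outcome: str,
               covariates=COX_COVARIATES, min_events: int = 10) -> pd.DataFrame:
    """Per-locus adjusted Cox screen; returns log HR, SE, HR, Wald p, BH q."""
    tcol, ecol = _outcome_columns(outcome)
    clin = clinical.set_index("sample_id").loc[list(matrix.columns)].reset_index()
    times = clin[tcol].to_numpy(float)
    events = clin[ecol].to_numpy(bool)
    if (times <= 0).any():
        raise CoxError("event/censoring times must be positive")
    if events.sum() < min_events:
        raise CoxError(f"need at least {min_events} events, got {int(events.sum())}")
    covs = []
    for cov in covariates:
        covs.append(grade_binary(clin["grade_group"]) if cov == "grade"
                    else clin[cov].to_numpy(float))
    Z = np.column_stack(covs) if covs else np.empty((len(clin), 0))
    Y = matrix.to_numpy(float)
    rows = []
    for k in range(Y.shape[0]):
        x = Y[k]
        if np.isnan(x).any() or np.ptp(x) == 0:
            rows.append((np.nan, np.nan, np.nan))
            continue
        X = np.column_stack([x, Z])
        try:
            beta, se, converged = cox_fit(times, events, X)
            if not converged or se[0] == 0:
                rows.append((np.nan, np.nan, np.nan))
            else:
                z = beta[0] / se[0]
                rows.append((beta[0], se[0], 2.0 * stats.norm.sf(abs(z))))
        except (CoxError, np.linalg.LinAlgError):
            rows.append((np.nan, np.nan, np.nan))
    res = pd.DataFrame(rows, columns=["log_hr", "se", "p"], index=matrix.index)
    res["hr"] = np.exp(res["log_hr"])
    res["q"] = np.nan
    ok = res["p"].notna()
    if ok.any():
        res.loc[ok, "q"] = bh_adjust(res.loc[ok, "p"].to_numpy())
    return res[["log_hr", "se", "hr", "p", "q"]]


def gene_calls(matrix: pd.DataFrame, fit) -> pd.DataFrame:
    """Categorical loss/neutral/gain calls for a locus matrix, from the
    cohort mixture fit applied to locus-level values."""
    from .mixture import call_values

    vals = matrix.to_numpy(float)
    out = np.full(vals.shape, None, dtype=object)
    flat = vals.ravel()
    okmask = ~np.isnan(flat)
    states = np.full(flat.shape, None, dtype=object)
    states[okmask] = call_values(flat[okmask], fit)
    out = states.reshape(vals.shape)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def km_logrank(gain: pd.Series, clinical: pd.DataFrame, outcome: str):
    """Kaplan-Meier curves and log-rank test for gain vs non-gain strata.

    ``gain`` is a boolean Series indexed by sample_id.  Returns
    ``(curves, statistic, p)`` where ``curves`` is a tidy frame of
    (stratum, time, at_risk, survival).
    """
    tcol, ecol = _outcome_columns(outcome)
    clin = clinical.set_index("sample_id").loc[gain.index]
    g = gain.to_numpy(bool)
    if g.sum() == 0 or (~g).sum() == 0:
        raise ValueError("both gain and non-gain strata must be non-empty")
    curves = []
    for label, mask in (("gain", g), ("no_gain", ~g)):
        kmf = KaplanMeierFitter()
        kmf.fit(clin[tcol][mask], clin[ecol][mask], label=label)
        tab = kmf.event_table
        surv = kmf.survival_function_[label]
        curves.append(
            pd.DataFrame(
                {
                    "stratum": label,
                    "time": tab.index.to_numpy(float),
                    "at_risk": tab["at_risk"].to_numpy(int),
                    "survival": surv.reindex(tab.index).to_numpy(float),
                }
            )
        )
    res = logrank_test(
        clin[tcol][g], clin[tcol][~g], clin[ecol][g], clin[ecol][~g]
    )
    return pd.concat(curves, ignore_index=True), float(res.test_statistic), float(res.p_value)


def frequency_of_gain(states: pd.Series) -> tuple[int, int, int]:
    """Count of gains, total informative samples, and the percentage
    rounded to the nearest integer."""
    s = states.dropna()
    n_gain = int((s == "gain").sum())
    total = int(len(s))
    pct = int(round(100.0 * n_gain / total)) if total else 0
    return n_gain, total, pct
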