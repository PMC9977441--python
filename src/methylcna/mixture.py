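"""Cohort-wide 3-component Gaussian mixture on segment means, segment
state calling, and percent genome altered (PGA).

The model
---------
Pooled over every sample in the cohort, segment mean log2 copy ratios are
modeled as a mixture of three normal components representing *lost*,
*copy-neutral* and *gained* genomic territory:

    x_j ~ sum_k pi_k N(mu_k, sigma_k^2),   k in {loss, neutral, gain}

fit by expectation-maximization, optionally weighting each segment by its
supporting bin count (segment means of long segments are more precise).
Components are relabeled after fitting so that mu_loss < mu_neutral <
mu_gain.  Each segment is then assigned the maximum-posterior state, and a
sample's PGA is the cumulative length of its non-neutral segments divided
by the genome size, times 100.

Samples in which no segment is called gained or lost get PGA 0 and an
``excluded`` flag; downstream correlation analyses drop them.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeModel

STATES = ("loss", "neutral", "gain")
_NEUTRAL = 1


@dataclass
class MixtureFit:
    """Fitted 3-component Gaussian mixture (loss / neutral / gain)."""

    weights: np.ndarray  # pi, sums to 1
    means: np.ndarray    # mu, ascending (log2 units)
    sds: np.ndarray      # sigma, per component
    log_likelihood: np.ndarray = field(repr=False)  # per-iteration trace
    n_iter: int = 0
    converged: bool = False
    degenerate: bool = False

    def posterior(self, x: np.ndarray) -> np.ndarray:
        """Posterior state responsibilities, one row per value of ``x``."""
        x = np.asarray(x, float)
        logp = (
            np.log(np.maximum(self.weights, 1e-300))[None, :]
            + stats.norm.logpdf(x[:, None], self.means[None, :], self.sds[None, :])
        )
        logp -= logp.max(axis=1, keepdims=True)
        p = np.exp(logp)
        return p / p.sum(axis=1, keepdims=True)


def _em(x, w, mu0, sd0, pi0, tol, max_iter, sigma_floor):
    mu, sd, pi = mu0.copy(), sd0.copy(), pi0.copy()
    wsum = w.sum()
    trace = []
    converged = False
    floored = False
    for it in range(max_iter):
        logcomp = (
            np.log(np.maximum(pi, 1e-300))[None, :]
            + stats.norm.logpdf(x[:, None], mu[None, :], sd[None, :])
        )
        m = logcomp.max(axis=1, keepdims=True)
        dens = np.exp(logcomp - m)
        tot = dens.sum(axis=1, keepdims=True)
        ll = float(np.dot(w, (np.log(tot[:, 0]) + m[:, 0])))
        trace.append(ll)
        r = dens / tot
        wr = w[:, None] * r
        nk = wr.sum(axis=0)
        pi = nk / wsum
        mu = (wr * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = (wr * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / np.maximum(nk, 1e-300)
        sd = np.sqrt(var)
        if (sd < sigma_floor).any():
            floored = True
            sd = np.maximum(sd, sigma_floor)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
    return mu, sd, pi, np.array(trace), converged, floored


def fit_mixture(
    segments: pd.DataFrame,
    weighting: str = "by_bins",
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    sigma_floor: float = 1e-3,
    max_restarts: int = 5,
) -> MixtureFit:
    """Fit the cohort mixture to pooled segment means.

    Parameters
    ----------
    segments
        Segment table (all samples pooled); needs ``seg_mean`` and, for the
        default weighting, ``n_bins``.
    weighting
        ``"none"``, ``"by_bins"`` (default; weight = supporting bin count)
        or ``"by_length"`` (weight = genomic length).
    seed
        Drives the quantile-jittered re-initialization used when a
        component's scale collapses to the floor.

    Initialization is at the 10th/50th/90th percentiles of the data with
    sigma = pooled SD / 2 and weights (0.15, 0.7, 0.15).  A fit whose
    scales stay on the floor after ``max_restarts`` jittered restarts is
    returned with ``degenerate=True`` (e.g. constant input collapses to a
    single effective component).
    """
    x = segments["seg_mean"].to_numpy(float)
    if len(x) < 30:
        raise ValueError("need at least 30 pooled segments to fit the mixture")
    if weighting == "none":
        w = np.ones_like(x)
    elif weighting == "by_bins":
        w = segments["n_bins"].to_numpy(float)
    elif weighting == "by_length":
        w = (segments["end"] - segments["start"]).to_numpy(float)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    w = w / w.mean()

    rng = np.random.default_rng(seed)
    pooled_sd = max(float(np.std(x)), sigma_floor)
    base_mu = np.quantile(x, [0.10, 0.50, 0.90])
    pi0 = np.array([0.15, 0.70, 0.15])
    sd0 = np.full(3, max(pooled_sd / 2.0, sigma_floor))

    best = None
    for attempt in range(max_restarts + 1):
        mu0 = base_mu if attempt == 0 else base_mu + rng.normal(0, pooled_sd / 4, 3)
        mu, sd, pi, trace, converged, floored = _em(
            x, w, np.sort(mu0), sd0, pi0, tol, max_iter, sigma_floor
        )
        if not np.isfinite(trace).all():
            continue
        cand = (mu, sd, pi, trace, converged, floored)
        if best is None or trace[-1] > best[3][-1]:
            best = cand
        if not floored:
            best = cand
            break
    if best is None:
        raise RuntimeError("EM failed to produce a finite log-likelihood")
    mu, sd, pi, trace, converged, floored = best
    order = np.argsort(mu)
    return MixtureFit(
        weights=pi[order],
        means=mu[order],
        sds=sd[order],
        log_likelihood=trace,
        n_iter=len(trace),
        converged=converged,
        degenerate=floored,
    )


def call_segments(segments: pd.DataFrame, fit: MixtureFit) -> pd.DataFrame:
    """Assign each segment its maximum-posterior state.

    Returns the segment table with posterior columns ``p_loss, p_neutral,
    p_gain`` and a categorical ``state``.  Posterior ties are broken toward
    neutral (a segment equidistant between two components is not called
    altered).
    """
    post = fit.posterior(segments["seg_mean"].to_numpy(float))
    hard = post.argmax(axis=1)
    tie = post[:, _NEUTRAL] >= post.max(axis=1) - 1e-12
    hard[tie] = _NEUTRAL
    out = segments.copy()
    out["p_loss"] = post[:, 0]
    out["p_neutral"] = post[:, 1]
    out["p_gain"] = post[:, 2]
    out["state"] = pd.Categorical.from_codes(hard, categories=list(STATES))
    return out


def call_values(values: np.ndarray, fit: MixtureFit) -> np.ndarray:
    """State calls (``loss``/``neutral``/``gain``) for arbitrary log2 values,
    e.g. gene-level copy number; same tie rule as :func:`call_segments`."""
    post = fit.posterior(np.asarray(values, float))
    hard = post.argmax(axis=1)
    tie = post[:, _NEUTRAL] >= post.max(axis=1) - 1e-12
    hard[tie] = _NEUTRAL
    return np.array(STATES, dtype=object)[hard]


def compute_pga(calls: pd.DataFrame, genome: GenomeModel) -> pd.DataFrame:
    """Per-sample percent genome altered from called segments.

    ``pga_gain`` (``pga_loss``) is the summed length of gained (lost)
    segments divided by the genome size, as a percentage; ``pga_total`` is
    their sum.  Samples with no altered segment are flagged ``excluded``.
    """
    for chrom, grp in calls.groupby("chrom"):
        if chrom not in genome:
            raise ValueError(f"segments on unknown chromosome {chrom!r}")
        if (grp["start"] < 0).any() or (grp["end"] > genome.length_of(chrom)).any():
            raise ValueError(f"segment outside bounds of {chrom}")
    g = float(genome.total_size)
    lengths = (calls["end"] - calls["start"]).astype(float)
    df = pd.DataFrame(
        {
            "sample_id": calls["sample_id"],
            "gain_len": np.where(calls["state"] == "gain", lengths, 0.0),
            "loss_len": np.where(calls["state"] == "loss", lengths, 0.0),
            "altered": (calls["state"] != "neutral").astype(int),
        }
    )
    agg = df.groupby("sample_id", sort=False).sum()
    out = pd.DataFrame(
        {
            "sample_id": agg.index,
            "pga_gain": agg["gain_len"].values / g * 100.0,
            "pga_loss": agg["loss_len"].values / g * 100.0,
            "n_altered_segments": agg["altered"].values.astype(int),
        }
    ).reset_index(drop=True)
    out["pga_total"] = out["pga_gain"] + out["pga_loss"]
    out["excluded"] = out["n_altered_segments"] == 0
    return out[
        ["sample_id", "pga_total", "pga_gain", "pga_loss", "n_altered_segments", "excluded"]
    ]
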