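"""Synthetic cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream models
assume, at desk scale:

* a shared genome partition per cohort (every annotated locus is its own
  segment; inter-locus gaps and extra random breakpoints form background
  segments);
* cohort-wide segment log2 ratios drawn from a 3-component loss/neutral/
  gain Gaussian mixture;
* planted loci whose alteration indicator is Bernoulli with probability
  logistic in the sample's ancestry fraction (gain when the somatic effect
  is positive, loss when negative);
* germline-flagged loci altered by the same law in a normal-tissue cohort
  (which otherwise carries no somatic alterations);
* censored time-to-event outcomes with exponential hazards scaled by gain
  status at a designated hazard locus plus clinical covariates;
* immune cell fractions whose Treg component is tied to each sample's true
  PGA through a Gaussian copula calibrated to a target Spearman rho.

Ancestry fractions are drawn from a two-component Beta mixture (one mode
near 0, one near 0.8) so the two self-identified groups are separable yet
overlap slightly, mirroring a cohort where group label and continuous
ancestry are highly but not perfectly correlated.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .genome import GenomeModel

CELL_TYPES = (
    "Treg", "Bcell", "CD4T", "CD8T", "NK",
    "Macrophage", "Neutrophil", "Eosinophil", "Endothelial", "Fibroblast",
)


@dataclass(frozen=True)
class LocusDef:
    """A planted (or null) locus.

    ``somatic_effect`` is the segment mean log2 ratio when the locus is
    altered (sign decides gain vs loss); 0 marks a null locus whose values
    follow the background mixture.  Alteration probability at ancestry
    fraction ``a`` is ``expit(base_logit + ancestry_slope * a)``.
    """

    locus_id: str
    chrom: str
    start: int
    end: int
    somatic_effect: float = 0.0
    base_logit: float = -0.85
    ancestry_slope: float = 0.0
    germline: bool = False

    def prob(self, ancestry) -> np.ndarray:
        return expit(self.base_logit + self.ancestry_slope * np.asarray(ancestry, float))


@dataclass(frozen=True)
class MixtureTruth:
    """Ground-truth mixture for background segment means (log2 units)."""

    means: tuple[float, float, float] = (-0.5, 0.0, 0.5)
    sds: tuple[float, float, float] = (0.08, 0.08, 0.08)
    weights: tuple[float, float, float] = (0.10, 0.80, 0.10)

    def __post_init__(self):
        if not (self.means[0] < self.means[1] < self.means[2]):
            raise ValueError("mixture means must satisfy loss < neutral < gain")
        if any(s <= 0 for s in self.sds):
            raise ValueError("mixture sds must be positive")
        if abs(sum(self.weights) - 1.0) > 1e-9 or any(w < 0 for w in self.weights):
            raise ValueError("mixture weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings; defaults are the study conditions.

    Cohort sizes follow a grade-matched two-group tumor cohort (145 + 145)
    with a 120-donor two-group normal-tissue reference (2:1 split).  The
    hazard locus acts on both outcomes with the given log hazard ratio per
    gain; baseline hazards and uniform administrative censoring over
    ``followup_max`` years are chosen to give an event-rich cohort so the
    outcome screens are informative at this scale.
    """

    n_tumor_group_a: int = 145  # high-ancestry group
    n_tumor_group_b: int = 145
    n_normal: int = 120
    normal_group_a_frac: float = 2.0 / 3.0
    loci: tuple[LocusDef, ...] = ()
    mixture: MixtureTruth = field(default_factory=MixtureTruth)
    hazard_locus: str | None = None
    hazard_log_hr: float = 0.8
    baseline_hazard_bcr: float = 0.12   # events per year
    baseline_hazard_met: float = 0.06
    followup_max: float = 15.0          # years of administrative censoring
    treg_pga_rho: float = 0.4           # target Spearman rho
    noise_sd: float = 0.05              # log2 noise on planted altered segments
    n_background_breaks: int = 10       # extra random breakpoints per chromosome
    seed: int = 0

    def __post_init__(self):
        if min(self.n_tumor_group_a, self.n_tumor_group_b, self.n_normal) < 0:
            raise ValueError("cohort sizes must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hazard_locus is not None and self.hazard_locus not in {
            l.locus_id for l in self.loci
        }:
            raise ValueError(f"hazard locus {self.hazard_locus!r} not among loci")


@dataclass
class TruthRecord:
    """Planted ground truth for every downstream stage."""

    samples: pd.DataFrame       # sample_id, cohort, group, ancestry, true_pga, ...
    alterations: pd.DataFrame   # samples x loci boolean indicators
    segment_states: pd.DataFrame  # samples x segments, int8 codes 0/1/2
    fractions: pd.DataFrame     # tumor samples x cell types
    loci: tuple[LocusDef, ...]
    config: SimConfig

    def analytic_prob(self, locus_id: str, ancestry) -> np.ndarray:
        """Closed-form alteration probability for a planted locus."""
        locus = next(l for l in self.loci if l.locus_id == locus_id)
        return locus.prob(ancestry)


@dataclass
class SyntheticCohort:
    segments: pd.DataFrame          # tumor segment table
    normal_segments: pd.DataFrame
    matrix: pd.DataFrame            # tumor loci x samples
    normal_matrix: pd.DataFrame
    clinical: pd.DataFrame          # tumor clinical incl. outcomes
    normal_clinical: pd.DataFrame
    annotation: pd.DataFrame        # BED-like locus table
    truth: TruthRecord


def _check_loci(loci, genome: GenomeModel) -> None:
    by_chrom: dict[str, list[LocusDef]] = {}
    for locus in loci:
        if locus.chrom not in genome:
            raise ValueError(f"locus {locus.locus_id} on unknown chromosome {locus.chrom}")
        if not 0 <= locus.start < locus.end <= genome.length_of(locus.chrom):
            raise ValueError(f"locus {locus.locus_id} outside chromosome bounds")
        by_chrom.setdefault(locus.chrom, []).append(locus)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda l: l.start)
        for prev, cur in zip(group[:-1], group[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"planted loci {prev.locus_id} and {cur.locus_id} overlap on {chrom}"
                )


def _partition(genome: GenomeModel, loci, n_breaks: int, rng) -> pd.DataFrame:
    """Shared segment grid: locus boundaries plus random background breaks."""
    rows = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        chrom_loci = sorted((l for l in loci if l.chrom == chrom), key=lambda l: l.start)
        cuts = {0, length}
        for l in chrom_loci:
            cuts.update((l.start, l.end))
        for b in rng.integers(1, length, size=n_breaks):
            if not any(l.start < b < l.end for l in chrom_loci):
                cuts.add(int(b))
        bounds = sorted(cuts)
        starts = {l.start: l.locus_id for l in chrom_loci}
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, s, e, starts.get(s) if (s in starts and any(
                l.start == s and l.end == e for l in chrom_loci)) else None))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "locus_id"])
    return df


_BIN_SIZE = 50_000


def _draw_segment_means(n_samples, grid, loci_by_id, ancestry, mixture, noise_sd,
                        rng, somatic: bool):
    """States (0/1/2) and observed means for every (sample, segment)."""
    S = len(grid)
    means = np.array(mixture.means)
    sds = np.array(mixture.sds)
    states = np.empty((n_samples, S), dtype=np.int8)
    values = np.empty((n_samples, S))
    locus_ids = grid["locus_id"].to_numpy(object)
    planted_cols = [
        j for j, lid in enumerate(locus_ids)
        if lid is not None and loci_by_id[lid].somatic_effect != 0.0
        and (somatic or loci_by_id[lid].germline)
    ]
    bg = np.setdiff1d(np.arange(S), planted_cols)
    if len(bg):
        if somatic:
            st = rng.choice(3, size=(n_samples, len(bg)), p=mixture.weights).astype(np.int8)
        else:
            st = np.ones((n_samples, len(bg)), dtype=np.int8)
        states[:, bg] = st
        values[:, bg] = rng.normal(means[st], sds[st])
    for j in planted_cols:
        locus = loci_by_id[locus_ids[j]]
        p = locus.prob(ancestry)
        altered = rng.random(n_samples) < p
        st = np.where(altered, 2 if locus.somatic_effect > 0 else 0, 1).astype(np.int8)
        states[:, j] = st
        vals = rng.normal(means[1], sds[1], n_samples)
        vals[altered] = rng.normal(locus.somatic_effect, max(noise_sd, 1e-12),
                                   altered.sum())
        values[:, j] = vals
    return states, values


def _segment_table(sample_ids, grid, values) -> pd.DataFrame:
    n, S = values.shape
    lengths = (grid["end"] - grid["start"]).to_numpy(np.int64)
    n_bins = np.maximum(lengths // _BIN_SIZE, 1).astype(np.int64)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, S),
            "chrom": np.tile(grid["chrom"].to_numpy(object), n),
            "start": np.tile(grid["start"].to_numpy(np.int64), n),
            "end": np.tile(grid["end"].to_numpy(np.int64), n),
            "n_bins": np.tile(n_bins, n),
            "seg_mean": values.ravel(),
        }
    )


def _draw_ancestry(rng, n, group: str) -> np.ndarray:
    if group == "A":
        return rng.beta(16.0, 4.0, n)
    return rng.beta(1.5, 15.0, n)


def simulate_cohort(config: SimConfig, genome: GenomeModel | None = None) -> SyntheticCohort:
    """Generate a complete synthetic cohort.

    Identical configs (including ``seed``) yield bit-identical outputs.
    """
    genome = genome or GenomeModel.toy()
    _check_loci(config.loci, genome)
    rng = np.random.default_rng(config.seed)
    grid = _partition(genome, config.loci, config.n_background_breaks, rng)
    loci_by_id = {l.locus_id: l for l in config.loci}

    n_a, n_b = config.n_tumor_group_a, config.n_tumor_group_b
    n_t = n_a + n_b
    tumor_ids = np.array([f"T{i + 1:04d}" for i in range(n_t)])
    tumor_group = np.array(["A"] * n_a + ["B"] * n_b)
    ancestry = np.concatenate(
        [_draw_ancestry(rng, n_a, "A"), _draw_ancestry(rng, n_b, "B")]
    )

    states, values = _draw_segment_means(
        n_t, grid, loci_by_id, ancestry, config.mixture, config.noise_sd, rng, somatic=True
    )
    segments = _segment_table(tumor_ids, grid, values)

    lengths = (grid["end"] - grid["start"]).to_numpy(float)
    g = float(genome.total_size)
    true_pga = ((states != 1) * lengths[None, :]).sum(axis=1) / g * 100.0

    # normal-tissue cohort: germline loci only
    n_na = int(round(config.n_normal * config.normal_group_a_frac))
    n_nb = config.n_normal - n_na
    normal_ids = np.array([f"N{i + 1:04d}" for i in range(config.n_normal)])
    normal_group = np.array(["A"] * n_na + ["B"] * n_nb)
    normal_anc = np.concatenate(
        [_draw_ancestry(rng, n_na, "A"), _draw_ancestry(rng, n_nb, "B")]
    )
    nstates, nvalues = _draw_segment_means(
        config.n_normal, grid, loci_by_id, normal_anc, config.mixture,
        config.noise_sd, rng, somatic=False,
    )
    normal_segments = _segment_table(normal_ids, grid, nvalues)

    annotation = grid.loc[grid["locus_id"].notna(),
                          ["chrom", "start", "end", "locus_id"]].reset_index(drop=True)
    # each locus is exactly one segment of the shared grid, so the locus
    # matrix is a column slice of the segment values (summarize_loci gives
    # the same numbers; see the generator tests)
    locus_cols = np.nonzero(grid["locus_id"].notna().to_numpy())[0]
    locus_index = pd.Index(grid["locus_id"].iloc[locus_cols], name="locus_id")
    matrix = pd.DataFrame(values[:, locus_cols].T, index=locus_index, columns=tumor_ids)
    normal_matrix = pd.DataFrame(nvalues[:, locus_cols].T, index=locus_index,
                                 columns=normal_ids)

    # clinical covariates and outcomes
    age = np.clip(rng.normal(62.0, 7.0, n_t), 40.0, 85.0)
    psa = np.exp(rng.normal(2.0, 0.6, n_t))
    grade_group = rng.choice([1, 2, 3, 4, 5], size=n_t, p=[0.30, 0.30, 0.20, 0.12, 0.08])
    grade_high = (grade_group >= 3).astype(float)

    if config.hazard_locus is not None:
        j = int(np.nonzero(grid["locus_id"].to_numpy(object) == config.hazard_locus)[0][0])
        hz_locus = loci_by_id[config.hazard_locus]
        gain_state = 2 if hz_locus.somatic_effect > 0 else 0
        hazard_gain = (states[:, j] == gain_state).astype(float)
    else:
        hazard_gain = np.zeros(n_t)
    eta = (
        config.hazard_log_hr * hazard_gain
        + 0.4 * grade_high
        + 0.02 * (age - 62.0)
    )
    clin = {"sample_id": tumor_ids, "group": tumor_group,
            "ancestry_fraction": ancestry, "age": age, "psa": psa,
            "grade_group": grade_group}
    for name, h0 in (("bcr", config.baseline_hazard_bcr),
                     ("met", config.baseline_hazard_met)):
        t_event = rng.exponential(1.0 / (h0 * np.exp(eta)))
        t_cens = rng.uniform(0.0, config.followup_max, n_t)
        clin[f"{name}_time"] = np.maximum(np.minimum(t_event, t_cens), 1e-6)
        clin[f"{name}_event"] = t_event <= t_cens
    clinical = pd.DataFrame(clin)

    # immune fractions: Treg tied to true PGA via a Gaussian copula whose
    # Pearson parameter is calibrated so the target is the Spearman rho
    rho_s = config.treg_pga_rho
    r = 2.0 * math.sin(math.pi * rho_s / 6.0)
    u_pga = stats.rankdata(true_pga) / (n_t + 1.0)
    z = stats.norm.ppf(u_pga)
    z_treg = r * z + math.sqrt(max(1.0 - r * r, 0.0)) * rng.normal(size=n_t)
    treg = stats.beta.ppf(stats.norm.cdf(z_treg), 2.0, 18.0)
    rest = rng.dirichlet(np.ones(len(CELL_TYPES) - 1), size=n_t) * (1.0 - treg)[:, None]
    fractions = pd.DataFrame(
        np.column_stack([treg, rest]), index=tumor_ids, columns=list(CELL_TYPES)
    )

    planted = [l for l in config.loci if l.somatic_effect != 0.0]
    alt_cols = {}
    locus_ids = grid["locus_id"].to_numpy(object)
    for l in planted:
        j = int(np.nonzero(locus_ids == l.locus_id)[0][0])
        alt_state = 2 if l.somatic_effect > 0 else 0
        alt_cols[l.locus_id] = np.concatenate(
            [states[:, j] == alt_state, nstates[:, j] == alt_state]
        )
    all_ids = np.concatenate([tumor_ids, normal_ids])
    alterations = pd.DataFrame(alt_cols, index=all_ids)

    seg_cols = [f"{c}:{s}-{e}" for c, s, e in zip(grid["chrom"], grid["start"], grid["end"])]
    truth = TruthRecord(
        samples=pd.DataFrame(
            {
                "sample_id": all_ids,
                "cohort": ["tumor"] * n_t + ["normal"] * config.n_normal,
                "group": np.concatenate([tumor_group, normal_group]),
                "ancestry": np.concatenate([ancestry, normal_anc]),
                "true_pga": np.concatenate([true_pga, np.zeros(config.n_normal)]),
                "hazard_gain": np.concatenate([hazard_gain.astype(bool),
                                               np.zeros(config.n_normal, bool)]),
            }
        ),
        alterations=alterations,
        segment_states=pd.DataFrame(
            np.vstack([states, nstates]), index=all_ids, columns=seg_cols
        ),
        fractions=fractions,
        loci=config.loci,
        config=config,
    )
    normal_clinical = pd.DataFrame(
        {"sample_id": normal_ids, "group": normal_group, "ancestry_fraction": normal_anc}
    )
    return SyntheticCohort(
        segments=segments,
        normal_segments=normal_segments,
        matrix=matrix,
        normal_matrix=normal_matrix,
        clinical=clinical,
        normal_clinical=normal_clinical,
        annotation=annotation,
        truth=truth,
    )


def simulate_betas(fractions: pd.DataFrame, signature: pd.DataFrame,
                   noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Beta matrix (CpGs x samples): fraction-weighted signature mixture
    plus Gaussian noise, clipped to [0, 1]."""
    if list(fractions.columns) != list(signature.columns):
        raise ValueError("cell types of fractions and signature do not match")
    F = fractions.to_numpy(float)
    if (F < 0).any() or not np.allclose(F.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("fractions must be non-negative and sum to 1 per sample")
    rng = np.random.default_rng(seed)
    B = signature.to_numpy(float) @ F.T
    if noise_sd > 0:
        B = B + rng.normal(0.0, noise_sd, B.shape)
    return pd.DataFrame(np.clip(B, 0.0, 1.0), index=signature.index,
                        columns=fractions.index)


def make_signature(n_cpgs: int = 600, cell_types=CELL_TYPES, seed: int = 0) -> pd.DataFrame:
    """Synthetic reference signature: CpGs x cell types, beta values drawn
    from a U-shaped Beta(0.5, 0.5) (methylation is largely bimodal)."""
    rng = np.random.default_rng(seed)
    vals = rng.beta(0.5, 0.5, size=(n_cpgs, len(cell_types)))
    idx = [f"cg{i:06d}" for i in range(n_cpgs)]
    return pd.DataFrame(vals, index=idx, columns=list(cell_types))


def default_loci(
    genome: GenomeModel | None = None,
    n_ancestry: int = 20,
    n_germline: int = 12,
    n_null: int = 500,
    hazard: bool = True,
    locus_width: int = 200_000,
) -> tuple[LocusDef, ...]:
    """Canonical planted-locus layout for the study conditions.

    Loci are evenly spaced across chromosomes: ``n_ancestry`` loss loci
    whose frequency rises with ancestry (induced mean slope about -0.3
    log2 per unit ancestry), ``n_germline`` strong germline CNVs shared
    with the normal cohort, one gained hazard locus (~40% prevalence), and
    ``n_null`` null loci following the background mixture.
    """
    genome = genome or GenomeModel.toy()
    specials: list[dict] = []
    for i in range(n_ancestry):
        specials.append(dict(kind="anc", locus_id=f"anc_{i + 1:03d}",
                             somatic_effect=-0.5, base_logit=-0.85,
                             ancestry_slope=2.5, germline=False))
    for i in range(n_germline):
        effect = 0.8 if i % 2 == 0 else -0.8
        specials.append(dict(kind="germ", locus_id=f"germ_{i + 1:03d}",
                             somatic_effect=effect, base_logit=-2.0,
                             ancestry_slope=5.0, germline=True))
    if hazard:
        specials.append(dict(kind="haz", locus_id="haz_001",
                             somatic_effect=0.5, base_logit=-0.4,
                             ancestry_slope=0.0, germline=False))
    for i in range(n_null):
        specials.append(dict(kind="null", locus_id=f"null_{i + 1:04d}",
                             somatic_effect=0.0, base_logit=0.0,
                             ancestry_slope=0.0, germline=False))

    n_total = len(specials)
    n_chrom = len(genome.chrom_names)
    loci: list[LocusDef] = []
    # round-robin across chromosomes so every kind of locus is spread out
    for ci, (chrom, length) in enumerate(zip(genome.chrom_names, genome.chrom_lengths)):
        mine = specials[ci::n_chrom]
        if not mine:
            continue
        pitch = length // (len(mine) + 1)
        width = min(locus_width, max(pitch // 2, 1000))
        for k, spec in enumerate(mine):
            start = (k + 1) * pitch - width // 2
            loci.append(LocusDef(
                locus_id=spec["locus_id"], chrom=chrom, start=int(start),
                end=int(start + width), somatic_effect=spec["somatic_effect"],
                base_logit=spec["base_logit"], ancestry_slope=spec["ancestry_slope"],
                germline=spec["germline"],
            ))
    return tuple(loci)


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """Study-condition configuration on the toy genome."""
    loci = overrides.pop("loci", None)
    if loci is None:
        loci = default_loci()
    hazard = "haz_001" if any(l.locus_id == "haz_001" for l in loci) else None
    cfg = SimConfig(loci=tuple(loci), hazard_locus=hazard, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg
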