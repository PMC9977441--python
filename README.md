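# methylcna

Copy number alteration analysis for methylation-array cohorts: from
bin-level log2 copy ratios to segment calls, percent genome altered,
ancestry-aware association screens with germline filtering, per-locus
survival screens, and immune-content deconvolution.

## Who this is for

Groups using Infinium-style methylation arrays as a by-product source of
somatic copy number alteration (sCNA) calls in tumor cohorts — in
particular cohorts with two self-identified groups plus continuous
genetic-ancestry estimates, censored clinical outcomes, and an interest
in whether global copy number burden tracks tumor immune content.

## The models at the core

**Segment calling and PGA.** Pooled over the cohort, segment mean log2
copy ratios `x` are modeled as a 3-component Gaussian mixture

    x ~ pi_loss N(mu_loss, s_loss^2) + pi_neut N(mu_neut, s_neut^2)
        + pi_gain N(mu_gain, s_gain^2),   mu_loss < mu_neut < mu_gain,

fit by EM (optionally weighting segments by supporting bin count). Each
segment gets its maximum-posterior state; per sample,

    PGA = 100 * (summed length of gained or lost segments) / genome size,

with gain and loss parts reported separately and zero-alteration samples
flagged and excluded from downstream correlations.

**Screens.** Per-locus linear models (copy number ~ group-or-ancestry +
age + PSA + binary Gleason grade, optional moderated t), per-locus Cox
proportional-hazards models (Efron ties), and Benjamini-Hochberg FDR
across loci. Loci significant in a normal-tissue cohort are treated as
germline CNV and subtracted from tumor hit lists. Cell-type fractions
come from sum-to-one non-negative least squares against a reference beta
signature and are correlated (Spearman) with PGA.

A fully seeded synthetic-cohort generator plants ground truth for every
stage (mixture states, logistic ancestry-dependent alteration
frequencies, germline loci shared with a normal cohort, a hazard locus
driving exponential outcomes, copula-linked Treg fractions), so the whole
pipeline is testable end to end. See `docs/methods.md` for model details
and assumptions.

## Worked example

```python
import numpy as np
import methylcna as m

cohort = m.simulate_cohort(m.default_config(seed=1))

fit = m.fit_mixture(cohort.segments, seed=1)
calls = m.call_segments(cohort.segments, fit)
pga = m.compute_pga(calls, m.GenomeModel.toy())
print(np.round(fit.means, 3), np.round(fit.weights, 3))
print("median PGA %.2f%%" % pga["pga_total"].median())

mat = m.prepare_matrix(cohort.matrix)
anc = m.screen_ancestry(mat, cohort.clinical)
hits = m.LocusSet(frozenset(anc.index[anc["q"] < 0.05]), "tumor_ancestry", 0.05)
germ = m.derive_germline_set(m.prepare_matrix(cohort.normal_matrix),
                             cohort.normal_clinical, fdr=0.001)
retained, removed, summary = m.filter_germline(hits, germ)
print(summary)

cox = m.cox_screen(mat, cohort.clinical, "bcr")
print("hazard locus HR %.2f, q %.2g" % (cox.loc["haz_001", "hr"],
                                        cox.loc["haz_001", "q"]))
```

prints

```
[-0.506  0.     0.506] [0.109 0.79  0.1  ]
median PGA 20.91%
{'n_hits': 34, 'n_removed': 12, 'n_retained': 22, 'pct_removed': 35}
hazard locus HR 6.46, q 7e-07
```

The recovered mixture means/weights sit on the planted truth
(±0.5 / 0 log2, 10/80/10%). The ancestry screen finds 34 significant
loci, of which 12 (35%) are flagged as germline by the normal-tissue
screen and removed — the planted layout has 20 true ancestry loci and 12
germline loci, plus ~2 expected false discoveries at FDR 0.05. The
hazard locus's fitted hazard ratio of 6.46 per log2 unit corresponds to
exp(0.8)/0.5-log2-gain planted truth (≈ 4.95 per unit), well inside its
Wald interval. Adding the deconvolution step and correlating estimated
Treg fractions with PGA gives Spearman rho ≈ 0.39 overall (planted 0.4).

A `methylcna` command-line interface exposes the same stages as
subcommands (`simulate`, `segment`, `pga`, `screen-race`,
`screen-ancestry`, `germline`, `filter`, `survival`, `km`, `deconv`,
`concord`, `run-all`, `report`); `methylcna run-all --out-dir out
--seed 1` runs the full pipeline on a simulated cohort and writes
per-stage TSVs plus a JSON report.

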