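# Methods

This note documents the models behind `methylcna`, the choices made where
the design was open, and what the synthetic cohorts do and do not show
about real data.

## Problem setting

Methylation arrays carry enough signal intensity information to estimate
relative DNA copy number. Starting from bin-level log2 copy ratios of
tumor against a pooled normal reference, the pipeline segments each
genome, calls each segment lost / copy-neutral / gained, summarizes copy
number to gene-level loci, and then asks three cohort-scale questions:
which loci vary with ancestry (after removing germline copy number
variation), which loci predict censored clinical outcomes, and whether
global copy number burden tracks immune cell content estimated from the
same arrays.

## Copy ratio processing

`normalize_to_reference` forms `log2(tumor / reference)` per bin, where the
reference is the per-bin mean over the pooled normal cohort (both ancestry
groups combined), then median-centers each sample so the modal copy state
sits at 0.

`segment_bins` is recursive binary segmentation. Within a segment the
candidate split maximizes a mean-shift statistic
`|mean_right - mean_left| * sqrt(n_l n_r / n) / sigma`, where `sigma` is a
robust noise scale from the median absolute deviation of first differences
(so the scale estimate is not inflated by the shift being tested). The
split is accepted when its normal-theory p-value, Šidák-adjusted for the
number of candidate split points scanned, is below `alpha` (default 0.01)
and both sides keep at least `min_bins` bins (default 5). This is
deliberately simpler than circular binary segmentation: it is
deterministic, has no permutation step, and produces the piecewise-
constant fits the downstream mixture stage needs. On noiseless input a
genuine mean difference is treated as an infinite statistic; round-off on
constant data is guarded by an absolute tolerance.

`summarize_loci` maps segments onto a BED annotation by length-weighted
averaging of overlapping segment means. Loci with no overlapping
territory are missing; loci missing in more than 10% of samples are
dropped before screening and the remainder are mean-imputed per locus
(`prepare_matrix`), keeping per-locus design matrices full rank.

## Mixture model and PGA

Pooled over the cohort, segment mean log2 ratios are modeled as a
3-component Gaussian mixture (loss / neutral / gain) fit by EM.
Numerical choices:

- initialization at the 10th/50th/90th percentiles of the data, component
  scale = pooled SD / 2, weights (0.15, 0.70, 0.15);
- segments weighted by their supporting bin count by default (segment
  means of long segments are more precise); `none` and `by_length` are
  available;
- scale floor 1e-3 log2 units; if a component collapses to the floor the
  fit restarts from quantile-jittered means (up to 5 times) and is
  otherwise returned flagged `degenerate` (e.g. constant input);
- convergence at relative log-likelihood change < 1e-8, max 500
  iterations; the likelihood trace is stored so monotonicity is testable.

Components are relabeled by mean order, so loss < neutral < gain always
holds. Calls are maximum-posterior with ties broken toward neutral; a
segment equally well explained by neutral and an altered state is not
called altered.

PGA per sample is `100 * (summed length of non-neutral segments) / genome
size`, split into gain and loss parts. Samples with no altered segment
are reported with PGA 0 and an `excluded` flag and are dropped from
PGA-based correlations; calling is pure argmax with no extra posterior
cutoff, so cohorts with strong signal may have no excluded samples at all.

## Association screens

Per-locus linear models share one design matrix, so a genome-wide screen
is a single least-squares solve. The predictor of interest is either the
two-level group label or the continuous ancestry fraction; covariates are
age, preoperative PSA (untransformed by default; a log flag exists) and
Gleason grade entered as binary low (GG1-2) vs high (GG3-5). Both
screens adjust for all three covariates by default. Group screens apply
empirical-Bayes variance moderation (per-locus residual variances shrunk
toward a pooled prior whose degrees of freedom and scale come from the
moments of `log s^2`; t statistics use the augmented degrees of freedom),
mirroring the moderated-t toolchain common for array screens; ancestry
screens default to plain least squares. Benjamini-Hochberg adjustment
runs across loci; default thresholds are 0.05 for tumor screens, 0.001
for the germline screen and 0.1 for Cox screens.

The germline filter runs the group screen on a normal-tissue cohort
(group-only design by default, since normal-tissue donors lack PSA and
grade), declares loci at q < 0.001 germline, and subtracts them from
tumor hit lists by locus id. Percentages in overlap summaries are rounded
to the nearest integer.

## Outcome models

The per-locus Cox screen fits a multivariable proportional-hazards model
(locus value + ancestry fraction + age + PSA + binary grade) by
Newton-Raphson with step-halving on the Efron-corrected partial
likelihood (tolerance 1e-8, max 50 iterations); standard errors come from
the inverse observed information. A locus that fails to converge or is
constant yields a NaN row rather than aborting the screen. The
implementation is validated against an independent Cox fitter in the test
suite. Kaplan-Meier / log-rank comparisons of gain vs non-gain strata use
`lifelines`. "Gain" for categorical analyses means mixture hard-call =
gain applied to locus-level values; with relative log2 data there is no
absolute copy count, so a fixed log2 cutoff is available only as an
option.

## Immune deconvolution

Cell-type fractions solve `min ||S f - b||^2` subject to `f >= 0`,
`sum f = 1`, per sample, where `S` is a CpG-by-cell-type reference beta
signature. The equality constraint is imposed through a heavily weighted
augmentation row inside a non-negative least-squares solve, then the
result is renormalized (the residual sum-to-one error before
renormalization is below 1e-8). This constrained least-squares
deconvolution is a deterministic method with the same input/output
contract as SVM-based deconvolution tools; it is not a reimplementation
of any of them. Spearman correlation (average ranks for ties) connects a
chosen cell type's fraction with PGA, overall and per group, after
dropping excluded samples.

## Synthetic cohorts

The generator plants ground truth for every stage on a toy genome of 5
chromosomes x 50 Mb — large enough to exercise multi-chromosome
bookkeeping, small enough that full-cohort runs take seconds. A shared
segment grid is built from locus boundaries plus 10 random background
breakpoints per chromosome; every annotated locus is exactly one segment.

Study conditions (the defaults):

- 145 + 145 tumors in two groups; 120 normal-tissue donors split 2:1,
  echoing an 80/40 normal cohort;
- ancestry fraction from a two-component Beta mixture, Beta(16, 4) for
  the high-ancestry group and Beta(1.5, 15) for the other, so group label
  and continuous ancestry are highly but not perfectly correlated (the
  within-group distribution of ancestry is a modeling choice, not an
  empirical estimate);
- background segment states drawn iid from the truth mixture, means
  (-0.5, 0, 0.5) log2, SDs 0.08, weights (0.10, 0.80, 0.10);
- planted loci altered with probability `expit(base_logit +
  slope * ancestry)`; the default ancestry loci (effect -0.5 log2,
  base logit -0.85, slope 2.5) induce a mean slope of about -0.3 log2 per
  unit ancestry; germline loci use a stronger, more bimodal law
  (effect +/-0.8, base logit -2, slope 5), consistent with common
  multi-allelic germline CNVs being larger than somatic dosage shifts;
- outcomes are exponential with hazard scaled by `exp(0.8 * gain)` at the
  hazard locus plus modest grade and age terms, under uniform
  administrative censoring over 15 years. Baseline hazards (0.12/yr
  recurrence, 0.06/yr metastasis) and a ~40% hazard-locus gain
  prevalence were set by a power calculation so that the per-locus Cox
  screen has roughly 95% per-seed power for the planted log HR of 0.8 at
  q < 0.1 — an event-rich cohort by design, since at that effect size a
  sparse-event cohort cannot support a genome-wide FDR-controlled
  detection claim at n = 290;
- Treg fractions are tied to true PGA through a Gaussian copula whose
  Pearson parameter is `2 sin(pi rho_s / 6)`, so the target is the
  Spearman rho itself (default 0.4); remaining cell types share
  `1 - Treg` via a flat Dirichlet;
- beta values are `signature x fractions` plus Gaussian noise clipped to
  [0, 1]; the bundled signature is synthetic, Beta(0.5, 0.5)-distributed
  (methylation is largely bimodal).

What the generator does **not** emulate: probe-level chemistry and
normalization artifacts, wave/GC biases, tumor purity and subclonality,
correlated germline haplotype structure, informative censoring, or a
realistic genome (real PGA medians are a few percent; the default mixture
weights give ~20%). Passing tests therefore demonstrate the statistical
machinery is correct under its own assumptions, not that the biological
effect sizes are realistic.

## Reproducibility

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configurations give bit-identical
cohorts. The validation suite runs the study conditions at desk scale:
the EM/PGA recovery cohort uses 290 samples and ~320k segments, screen
calibration uses 2,000 null loci across 50 seeds, the Cox recovery uses
20 seeds with ~100 null loci each, and deconvolution round-trips use a
600-CpG, 10-cell-type signature.

## Known limitations

- The EM is cohort-pooled; per-sample mixtures (differing purity/ploidy)
  are out of scope.
- Binary segmentation without permutation p-values can over- or
  under-split at low signal-to-noise relative to CBS.
- The moderated-t prior assumes a common variance trend across loci.
- Set filtering matches loci by annotation id only; coordinate-level
  fuzzy matching between platforms is not attempted.
- The deconvolution assumes the signature spans the tissue's cell types;
  unmodeled types bias fractions toward the nearest modeled profile.
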