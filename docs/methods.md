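# Methods

This note documents the statistical models, default parameters, numerical
choices and known limitations of `exprsurv`. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Relative expression

Relative quantification uses the single-reference ΔCt rule,
`ratio = 2^−(Ct_target − Ct_reference)`: one PCR cycle equals a factor of
two in template abundance, and no calibrator sample is assumed. Plots
against a healthy-donor cohort often rescale ratios to the donor median;
this is provided as an explicit, separate option
(`rescale_to_reference_median`) rather than silently applied. Efficiency
correction and multi-reference normalization are out of scope.

## Group comparisons

All tests are two-sided. The Mann–Whitney U test uses midranks throughout;
in `auto` mode it computes the exact permutation p by enumeration when both
groups have n ≤ 10 and there are no ties, otherwise the normal
approximation with tie correction and (by default) a 0.5 continuity
correction toward the mean. `exact` mode enumerates midrank assignments
directly (ties allowed) up to C(n+m, n) ≤ 5·10^5. The two-sided exact p
counts arrangements at least as extreme as |U − nm/2|. Welch's t is the
default t variant (pooled available); Spearman's ρ is the Pearson
correlation of midranks with the t approximation for p. Cohort-level
comparisons are pairwise across label levels (with an optional level-merge
to mirror favorable-versus-rest analyses), complete-case per comparison,
and report group sizes, medians and means alongside the statistic — both
location summaries because skewed expression data make them diverge.

## Survival core

**Kaplan–Meier.** Product-limit estimate over distinct event times;
censorings at an event time remain at risk for that time's events. With no
censoring the estimate telescopes to the empirical survival function
(verified to float round-off). **Median survival is the smallest event
time with S(t) ≤ 0.5**, reported as an explicit "undefined" (None) when
the curve never reaches 0.5 — the convention matters and other conventions
exist, so it is stated wherever a median is exported.

**Log-rank.** Two-group statistic with the hypergeometric variance at each
distinct event time, χ² with 1 df. For a binary covariate and *tie-free*
times it equals the Cox score statistic under Breslow tie handling
exactly; with tied event times the hypergeometric variance carries an
(r−d)/(r−1) factor the score information lacks, so the numerical
equivalence tests use continuous times.

**Cox proportional hazards (single covariate).** Newton–Raphson
maximization of the partial likelihood, Efron tie correction by default
(Breslow available, and required for the log-rank equivalence). The
covariate is centered for conditioning; risk-set sums are reverse
cumulative sums over time-sorted records, O(n) per evaluation.
Numerical choices:

* convergence is declared on the information-scaled gradient — effectively
  the Newton step in β units — at 1e-8, with at most 50 iterations. An
  absolute gradient threshold is not meaningful across sample sizes: at
  n ≈ 2000 the partial-likelihood gradient's floating-point noise exceeds
  1e-8.
* step-halving rejects only steps that decrease the log partial likelihood
  beyond its floating-point resolution (1e-9 relative), so the likelihood
  is non-decreasing across accepted steps up to round-off.
* monotone likelihood (perfect separation) is reported as a non-converged
  fit with a diagnostic warning — detected by a diverging estimate
  (|β| > 30 during iteration, or |β| > 15 / SE > 50 at a flat optimum) —
  never as an exception, because a cutoff scan must be able to record and
  skip such candidates.
* p-values: Wald by default; score and likelihood-ratio p are also
  reported on every fit since platforms differ in which they print.

**Benjamini–Hochberg.** Step-up adjusted values
`q_(i) = min_{j≥i} p_(j)·m/j` clipped to 1, returned in input order;
verified against the brute-force definition and permutation-invariant.

## The cutoff scan

Candidates are the *observed* unique expression values within the
quantile-restricted range (default [Q1, Q3], linear-interpolation
convention — declared in config and echoed into every report because
quantile conventions shift candidate sets). Observed values are the only
points where the stratification changes, so "all available cut-offs"
reduces to them. `min_group_size` (default 10) removes candidates leaving
a degenerate tail stratum. The strata are low = {x ≤ v} vs high reference,
so HR > 1 encodes "low expression is adverse".

The FDR family is the candidate set of one scan (one marker, one cohort,
one endpoint); subgroup scans adjust within each stratum independently.
Selection takes the minimum FDR-adjusted value; exact FDR ties (common,
because the step-up minimum flattens runs of candidates) are broken by the
highest hazard ratio, then lower raw p, then smaller cutoff — fully
deterministic. Non-converged candidates stay in the emitted table but are
excluded from selection with a logged warning.

**Why the BH step exists, and how it behaves.** On null cohorts (n = 200)
the uncorrected minimum-p rule rejects at far above its nominal level
(≈ 25–28% in the packaged simulations) — the classic anti-conservatism of
optimal-cutpoint searches. The BH-selected rule's family-wise error under
the global null is the Simes event `min q ≤ α`, which equals α under
independence but is *conservative under the strong positive dependence of
overlapping cutoff strata*: the packaged 1000-cohort simulation measures
≈ 0.02 at α = 0.05 rather than the nominal 0.05. This conservatism is a
genuine property of the procedure, not an implementation artifact — the
per-cutoff tests themselves are calibrated (single fixed-cutoff null
rejection ≈ 0.046, and log-rank/Cox match reference implementations to
1e-8/1e-6). A maximally-selected-rank-statistics correction
(Lausen–Schumacher) would be the exact alternative; it is deliberately out
of scope because the BH procedure is the one under study here.

With a true hazard step (HR = 2 at expression 0.33), the selected cutoff
concentrates on the truth as n grows (median absolute error shrinking
across n = 200/500/2000) and the selected-cutoff HR averages within 10% of
2.0 at n = 2000. At smaller n the selected HR is upward-biased (winner's
curse of selecting the most significant cutoff) — visible in the packaged
simulations and worth remembering when reading single-cohort scan output.

## Synthetic cohorts

The generator emulates the statistical structure such analyses assume,
with ground truth carried beside (never inside) the table:

* **Expression**: log-normal, default μ = −1.1, σ = 0.9 on the log scale —
  median 0.33 with a typical 39-sample range of ~0.03–1.4, matching the
  right-skewed, widely dispersed ratios reported for AML qRT-PCR cohorts;
  truncated below at 0.01.
* **Survival**: exponential with hazard 0.03/month times exp(step effect);
  the effect acts as a *step* at the latent cutoff (default: two-fold
  hazard below 0.33) because the scan searches for exactly such a
  threshold; a linear-in-log-expression mechanism is available for
  robustness checks. EFS adds an independent second event process
  (0.015/month, same step), so EFS ≤ OS by construction.
* **Censoring**: independent exponential (0.01/month) plus a 120-month
  administrative cap — the simplest mechanism satisfying the
  non-informative censoring KM/Cox assume. Defaults give roughly two
  thirds of patients an observed event, the event fraction reported for
  the real 830-sample transcriptome cohorts. The real cohorts' censoring
  distribution is unknown; this is a stand-in, not an inference.
* **Mutation flags**: independent Bernoulli (FLT3-ITD 0.25, NPM1 0.30,
  CEBPA 0.08 — standard AML frequencies), with optional
  subgroup-specific step effects for targeted-effect simulations.
* **CR**: logistic in log expression (intercept 1.5, slope 1.0), giving a
  monotone CR/non-CR separation without asserting any particular
  published model.

What the generator does *not* emulate: probe-level microarray structure,
RNA-seq count noise, correlated mutations, non-proportional hazards,
informative censoring, or cohort batch effects. Passing recovery and
calibration tests therefore demonstrates correctness of the *procedure*
under its own assumptions, not robustness to real-data violations of them.

Determinism: one named RNG per generated object, seed recorded in the
sidecar metadata; identical spec + seed reproduces byte-identical files.

## Assay kinetics

Growth: λ = (ln Nt − ln N0)/(t − t0) per hour, t_d = ln 2/λ; negative λ is
allowed (shrinking culture) but has no doubling time, signalled as an
explicit error. Multi-timepoint series extend the two-point formula either
by averaging per-interval λ or by log-linear least squares of ln(count) on
time (default for noisy data — it pools all points and has visibly lower
variance in the packaged simulations). Noise is multiplicative log-normal
with unit mean at the stated CV.

Dose–response: 4PL on log-dose,
`r = bottom + (top−bottom)/(1+(ic50/d)^hill)`, so the fitted curve passes
through (bottom+top)/2 at the fitted IC50 by construction and hill > 0 is
an increasing curve. The model choice follows the de-facto standard of
curve-fitting software for such assays. Fitting is Levenberg–Marquardt
least squares from a 12-point multi-start grid (hill × log-IC50 quantiles);
total failure returns a non-converged result carrying diagnostics rather
than raising. Percent-of-control normalization before fitting is a config
switch (off by default). Curve comparison reports the IC50 ratio and
per-dose fitted differences with residual-resampling bootstrap percentile
CIs; `n_boot=0` gives point estimates only. IC50 precision is
information-limited: with 3% absolute response noise on a triplicate
8-point dilution bracketing the IC50 and a switch-like slope (hill 1.5,
typical of chemotherapy-induced apoptosis readouts), median recovery error
is ≈ 4% — the same error a reference least-squares fit started at the
truth attains, i.e. the estimator is efficient at the design's information
content. Shallower curves or single replicates degrade this roughly as
1/(hill·√replicates).

## Pipeline and I/O

Cohort tables are delimited text with a header; missing values are empty
or "NA"; a column mapping renames user columns onto canonical fields. Rows
violating invariants (non-positive times, unparseable flags) are rejected
individually with their line numbers logged — no silent drops; analyses
use complete cases per analysis, consistent with studies that report
per-analysis n. Ct pairs are converted to relative expression at load when
no ratio column is present. Time units are fixed: months for survival,
hours for growth. FAB-M3 exclusion is a pre-scan row filter
(`exclude_fab_m3`). Every report bundle echoes the verbatim config, its
hash and all seeds; identical config + seed reproduces byte-identical
bundles (timestamps are confined to logs).

## Known limitations

* Single-covariate Cox only; "multivariate" mutation analyses are
  implemented as stratified subgroup scans (independent scans within each
  mutation stratum), which is how the source analyses read, not as a joint
  model. No time-varying covariates, frailty, or competing risks.
* The null calibration of the scan is conservative (above); users wanting
  exact cutpoint-selection p-values need the Lausen–Schumacher family of
  corrections.
* Exact Mann–Whitney enumeration is limited to small samples by design.
* The 4PL fit assumes homoscedastic additive noise; strongly
  heteroscedastic readouts would need weighting that is not provided.
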