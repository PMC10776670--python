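# exprsurv

Expression-biomarker survival stratification for clinical cohorts, built
around the analysis pipeline used to relate a gene's mRNA expression level
(e.g. *PPP1R13B*/ASPP1 in acute myeloid leukemia) to treatment response and
survival: qRT-PCR relative quantification and group comparisons, an
exhaustive quartile-restricted cutoff scan with Cox proportional-hazards
modelling and Benjamini–Hochberg FDR selection, mutation-subgroup survival
analyses, and the in-vitro readouts that accompany such studies (growth
doubling times, 4PL dose–response IC50s). A synthetic-cohort generator with
known ground truth makes every stage testable without any external data.

## The core procedure

A continuous biomarker must be dichotomized to stratify survival, but the
cutoff is not known a priori. The package implements the optimal-cutpoint
scan:

1. **Candidates.** Every distinct observed expression value `v` with
   `Q1 ≤ v ≤ Q3` (linear-interpolation quantiles) defines strata
   low = {x ≤ v}, high = {x > v}; candidates leaving a stratum below
   `min_group_size` are dropped.
2. **Per-cutoff model.** A single-covariate Cox proportional-hazards fit of
   the low-vs-high indicator (Efron ties, Newton–Raphson on the partial
   likelihood) gives a hazard ratio and Wald p-value per candidate
   (log-rank p is available instead). HR > 1 means *low expression is
   adverse*.
3. **Multiplicity.** The minimum p over a scan is strongly anti-conservative
   (on null cohorts it rejects at >25% instead of 5%), so the whole
   candidate family is Benjamini–Hochberg adjusted:
   `q_(i) = min_{j≥i} p_(j)·m/j`.
4. **Selection.** The cutoff minimizing the FDR-adjusted value is selected;
   FDR ties are broken by the **highest hazard ratio**, residual ties by
   lower raw p, then smaller cutoff. Kaplan–Meier curves of the selected
   strata (with median survival under the S(t) ≤ 0.5 convention) are
   attached.

Supporting statistics are written from scratch and oracle-tested: the
Kaplan–Meier product-limit estimator, the two-group log-rank test (equal to
the Cox score statistic for a binary covariate with Breslow ties), the Cox
partial-likelihood machinery, BH-FDR, an exact small-sample Mann–Whitney U
test, Welch/pooled t, and Spearman correlation. Assay kinetics implement
λ = (ln Nt − ln N0)/(t − t0), t_d = ln 2 / λ, and 4PL dose–response fitting
`r(d) = bottom + (top−bottom)/(1+(ic50/d)^hill)` with multi-start least
squares and residual-bootstrap curve comparison.

## Worked example

```python
import exprsurv as es

cohort = es.generate_cohort(es.CohortSpec(n_patients=830, seed=7))
outcome = es.scan(cohort, es.ScanConfig())
sel = outcome.selected
print(sel.cutoff, sel.hazard_ratio, sel.fdr_q, outcome.selection_reason)
```

prints (see `examples/03_cutoff_scan.py` for the annotated version):

```
candidates scanned : 414
selected cutoff    : 0.324  (truth: 0.33)
strata             : n_low=455, n_high=375
hazard ratio       : 1.72  (truth: 2.0; low vs high, >1 = low is adverse)
p / FDR q          : 4.59e-12 / 4.11e-10
selection reason   : hr_tiebreak
median OS low/high : 10.9 / 19.0 months
```

The scan recovers the generating step (cutoff 0.33, two-fold hazard) from
830 simulated patients: low expressors die at almost twice the rate, and
their median overall survival is 8 months shorter. The `examples/`
directory has one short script per capability (simulation, group
comparisons, cutoff scan, subgroup scans, growth kinetics, dose–response).

A thin CLI mirrors the library:

```bash
exprsurv simulate cohort --seed 7 --out cohort.tsv
exprsurv cutscan --input cohort.tsv --out report/
exprsurv growth --input counts.tsv
exprsurv ic50 --input doses.tsv
```

## Scope

Consumes per-sample tables (expression or Ct pairs, survival times and
event flags, mutation flags, categorical labels). It does not download or
parse GEO/TCGA repositories, derive ELN risk labels from genetics, model
morphology (FAB M3 exclusion is a row filter), or implement
maximally-selected-rank-statistic corrections — the BH procedure above is
the implemented and calibrated correction. See `docs/methods.md` for
models, assumptions, numerical choices, and known limitations.
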