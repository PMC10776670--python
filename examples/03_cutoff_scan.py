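"""The headline analysis: quartile-restricted exhaustive cutoff scan.

Every distinct observed expression value inside the interquartile range is
tried as a low/high survival cutoff; a Cox model per cutoff gives p-values
that are Benjamini-Hochberg adjusted across the scan, and the minimum-FDR
cutoff is selected (ties broken by the highest hazard ratio).
"""

import exprsurv as es

spec = es.CohortSpec(n_patients=830, seed=7)  # transcriptome-cohort scale
cohort = es.generate_cohort(spec)

outcome = es.scan(cohort, es.ScanConfig())

print(f"candidates scanned : {len(outcome.results)}")
sel = outcome.selected
print(f"selected cutoff    : {sel.cutoff:.3f}  (truth: {spec.true_cutoff})")
print(f"strata             : n_low={sel.n_low}, n_high={sel.n_high}")
print(f"hazard ratio       : {sel.hazard_ratio:.2f}  (truth: 2.0; low vs high, >1 = low is adverse)")
print(f"p / FDR q          : {sel.p_value:.2e} / {sel.fdr_q:.2e}")
print(f"selection reason   : {outcome.selection_reason}")
print(f"median OS low/high : {outcome.km_low.median and round(outcome.km_low.median, 1)} / "
      f"{outcome.km_high.median and round(outcome.km_high.median, 1)} months")

# The selected cutoff should sit near the generating step (0.33) and the
# hazard ratio near the generating two-fold effect; the KM medians show
# the survival separation the cutoff induces.
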