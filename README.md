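# dietval

Validation of dietary assessment instruments against doubly labelled water
(DLW), packaged as a reusable, tested analysis pipeline with a synthetic
cohort generator — for nutrition epidemiologists who need the full chain
from raw isotope enrichments to misreporting prevalence, agreement and
ranking statistics, with every step reproducible from a seed.

Self-reported energy intake (EI) from food records and food-frequency
questionnaires (FFQs) is systematically biased. The objective benchmark is
total energy expenditure (TEE) measured with DLW: in weight-stable adults
EI should equal TEE. This package implements that comparison end to end:

1. **DLW engine** — the multipoint method. For each isotope the excess
   enrichment above the subject's pre-dose background decays as
   `E(t) = E0 · exp(-k t)`; ordinary least squares of `log E` on `t` gives
   the elimination constants `k_O`, `k_H` and back-extrapolated intercepts.
   Dilution spaces follow from tracer dose over intercept atom-fraction
   excess, and CO₂ production from the two-pool equation

   `rCO₂ = (N/2.078)(1.007 k_O − 1.041 k_H) − 0.0246 · 1.05 N (1.007 k_O − 1.041 k_H)`

   with `N` the scaled ¹⁸O dilution space. Energy expenditure comes from
   `rCO₂` via the Weir expression at a configured food quotient. QC flags
   cover the `N_H/N_O` pool-ratio window, ±1 kg weight stability, and
   diverging log-scale residuals.

2. **Misreporting** — Goldberg-type 95% confidence limits around EI:TEE = 1,

   `1 ± z·sqrt(CV_EI²/d + CV_TEE²)/100`,

   with `CV_TEE` = 8.4%, `CV_EI` = 20.6% and `d` = 4 recording days this
   gives cut-offs (0.73, 1.27); for an FFQ (`d → ∞`) it gives (0.83, 1.17).
   Reporting accuracy is `100 · EI/TEE`.

3. **Energy adjustment** — the residual model (nutrient regressed on
   energy; residual plus fitted value at mean energy) and energy density
   (unit/MJ), after a per-variable log or square-root transformation chosen
   by minimum absolute skewness.

4. **Agreement and ranking** — Bland–Altman limits of agreement with a
   proportional-bias trend test, the calibration slope of TEE on EI with
   its 95% CI, Wilcoxon signed-rank paired comparisons, crude Spearman and
   energy-adjusted Pearson correlations, and tertile/quartile
   cross-classification with Cohen's weighted κ.

5. **Synthetic cohort** — because individual-level study data are not
   public, a seeded generator emulates the cohort structure: true TEE
   ~ 10.8 (SD 2.7) MJ/d, instrument reporting accuracy ~ truncated normal
   with means 0.80/0.82 and SDs 0.23/0.33, within-subject CVs of 20.6%
   (record EI) and 8.4% (TEE), macronutrient energy shares, and isotope
   curves built by inverting the engine's own forward model so a noise-free
   cohort closes the loop exactly.

## Worked example

```bash
dietval all --seed 1 --out runs/demo
```

prints (also written to `runs/demo/report.txt`, with full-precision JSON in
`report.json` and per-stage CSV tables alongside):

```
Dietary instrument validation report
======================================
Cohort: 200 subjects ({'female': 100, 'male': 100}), DLW subsample n=40
TEE (DLW): mean 11.2 MJ/d (95% CI 10.2, 12.2)
EI record: mean 9.3 MJ/d (95% CI 8.0, 10.6); EI-TEE -1.9 (SD 2.7) MJ/d
EI ffq: mean 9.3 MJ/d (95% CI 7.7, 10.9); EI-TEE -2.0 (SD 3.8) MJ/d
Misreporting ffq: limits (0.83, 1.17); under 47.5%, plausible 37.5%, over 15.0%; accuracy 81.5% (SD 33.2)
Misreporting record: limits (0.73, 1.27); under 40.0%, plausible 57.5%, over 2.5%; accuracy 82.1% (SD 22.7)
Bland-Altman record_vs_dlw: mean diff -1.9 (SD 2.7), LoA (-7.2, 3.3), trend P=0.01
  calibration slope 0.57 (95% CI 0.40, 0.73)
Bland-Altman ffq_vs_dlw: mean diff -2.0 (SD 3.8), LoA (-9.4, 5.5), trend P=0.00
  calibration slope 0.40 (95% CI 0.24, 0.55)
Bland-Altman record_vs_ffq: mean diff -0.0 (SD 4.2), LoA (-8.3, 8.2), trend P=0.05
Ranking record_vs_dlw (energy, 3 bins): same 67.5%, opposite 2.5%, kappa_w 0.61
Ranking ffq_vs_dlw (energy, 3 bins): same 55.0%, opposite 5.0%, kappa_w 0.44
Ranking record_vs_ffq (energy, 3 bins): same 46.5%, opposite 12.5%, kappa_w 0.26
Run: seed=1 config_hash=5b44174c793e7a91
```

Reading it: the simulated record under-reports energy by 1.9 MJ/d on
average (accuracy 82%), 40% of subjects fall below the 0.73 Goldberg
cut-off, and the calibration slope of 0.57 means a 1 MJ/d increase in
reported intake corresponds to only 0.57 MJ/d of measured expenditure.
The FFQ shows wider limits of agreement and weaker ranking (κ_w 0.44 vs
0.61), the expected signature of its larger reporting-error variance.

The same analysis runs stage by stage (`dietval simulate|dlw|misreport|
adjust|agree|report`) on the CSV files in the run directory, so measured
(non-simulated) enrichment and intake tables in the same schemas can be
dropped in at any stage. From Python:

```python
from dietval import CohortConfig, run_pipeline
report = run_pipeline(CohortConfig(seed=1), "runs/demo")
```

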