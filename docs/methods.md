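# Methods

## Scope and model

The package implements the complete analysis chain of a dietary-instrument
validation study: doubly-labelled-water (DLW) total energy expenditure
(TEE), Goldberg-limit misreporting classification, residual-model and
density energy adjustment, and agreement/ranking statistics between two
instruments (a multi-day food record, `record`, and a food-frequency
questionnaire, `ffq`) and between each instrument and DLW. Because the
underlying study data are not public, a seeded synthetic-cohort generator
reproduces the statistical structure those analyses assume; it is
first-class, tested code, not a fixture.

## DLW engine

**Elimination fits.** Excess enrichment (ppm above the subject's own
pre-dose background) is assumed mono-exponential. OLS of `log E` on time
gives `k = −slope` and the back-extrapolated intercept `E0 = exp(a)`.
Samples with non-positive excess are excluded with a warning; at least two
usable points at distinct times are required. The back-extrapolated
intercept (multipoint convention), not a plateau sample, defines the
dilution space.

**Dilution spaces.** Tracer amounts are computed from the dose mass, the
mass fractions of the two labelled waters (defaults 0.05 for ²H₂O at 99.9
atom% and 0.10 for H₂¹⁸O at 10 atom%, per gram of dose mixture), and
purity-weighted component molar masses. `N = tracer moles / atom-fraction
excess` with two atom sites per water molecule for hydrogen and one for
oxygen, in moles of body water.

**CO₂ production and energy.** The two-pool multipoint form

    rCO2 = (N/2.078)(1.007 kO − 1.041 kH) − 0.0246 · rGf,
    rGf  = 1.05 · N (1.007 kO − 1.041 kH),

with `N = n_O / 1.01` by default (`n_H / 1.04` available; all constants
configurable in `DlwConstants`). Energy from rCO₂ uses the Weir
expression `EE = VCO2 · (1.106 + 3.941/FQ)` with CO₂ at 22.26 l/mol and
kcal→MJ conversion; the food quotient FQ defaults to 0.85 (typical mixed
Western diet) and is configurable per run. A non-positive rate difference
`1.007 kO − 1.041 kH` marks the subject invalid rather than producing a
negative TEE.

**Quality control.** Three flags: dilution-space ratio `n_H/n_O` outside
[1.00, 1.07]; pre/post body-weight difference beyond ±1 kg (weight
stability is what licenses EI = TEE); and a diverging-residual screen on
each elimination curve. The residual screen uses *externally* (leave-one-
out) studentized residuals: with four-point curves an internally
studentized residual is bounded by √(n−2) ≈ 1.4 and can never flag, while
the deleted residual is t(n−3)-distributed and heavy-tailed, so a fixed
cut-off either never fires or fires constantly. The default threshold is
therefore the Bonferroni outlier-test critical value `t(n−3, 1−α/(2n))`
with α = 0.01; a fixed numeric threshold can be configured instead.

## Misreporting

Confidence limits around EI:TEE = 1: `1 ± z·sqrt(CV_EI²/d + CV_TEE²)/100`,
CVs in percent, z = 2. Defaults CV_TEE = 8.4%, CV_EI = 20.6%, d = 4
(record); d = ∞ for the FFQ leaves only the TEE term. These yield the
cut-off pairs (0.73, 1.27) and (0.83, 1.17) after 2-decimal rounding.
Classification uses the rounded limits by default (matching how such
thresholds are reported and applied), with an unrounded mode available;
comparisons are strict, so a ratio exactly on a limit is plausible.
Cohort reporting-accuracy summaries use the sample (n−1) SD. Group-level
Goldberg variants with between-subject CV terms and PAL-stratified
cut-offs are out of scope.

## Energy adjustment

Each nutrient × instrument series is transformed (log or square root,
whichever minimises absolute sample skewness; ties to log) and then
adjusted by the residual model: OLS of transformed nutrient on energy,
adjusted value = residual + fitted value at the mean energy. The adjusted
series is exactly orthogonal to energy and the operation is idempotent.
Zeros under log (chiefly alcohol, which the generator zero-inflates) get
an offset of half the smallest positive observation, recorded per
variable. Transformation choice is pooled across sexes so both strata
share a scale; the adjustment itself runs within sex strata by default
(pooled mode available), since intake tables are conventionally
sex-stratified. The order is transform-then-adjust, the standard
residual-model practice. Energy density (`unit/MJ`) is provided as the
crude alternative used for Bland–Altman comparisons of nutrients.

## Agreement and ranking

* **Bland–Altman**: differences x−y, limits mean ± 1.96 sample SD;
  proportional bias ("P for trend") is the two-sided t test of the OLS
  slope of difference on pairwise mean.
* **Calibration slope**: OLS of measured TEE on reported EI; 95% CI from
  the slope SE and the t quantile at n−2 df.
* **Wilcoxon signed-rank**: zero differences dropped (and counted); exact
  null distribution for ≤ 25 untied non-zero differences, tie-corrected
  normal approximation with continuity correction otherwise; an all-zero
  vector is flagged degenerate rather than tested.
* **Correlations**: Spearman (midrank ties) on crude intakes, Pearson on
  transformed, energy-adjusted values. EI-vs-TEE correlations use
  untransformed energy.
* **Quantile bins**: boundaries at sample quantiles i/k (linear
  interpolation); a value exactly on a boundary goes to the lower bin — a
  deterministic, documented tie rule. Energy uses tertiles, nutrients
  quartiles.
* **Cross-classification**: same = diagonal, adjacent = |Δbin| = 1,
  opposite = the two extreme corner cells only.
* **Weighted κ**: `1 − Σw·p_obs / Σw·p_exp` with disagreement weights
  `|i−j|/(k−1)` (linear, default) or squared (quadratic); expectation from
  margin products. Linear is the common default for ordinal diet
  quantiles; the scheme is recorded in every output row.

## Synthetic cohort

The generator encodes the study conditions the analyses assume:

| parameter | default | basis |
|---|---|---|
| n subjects / DLW subsample | 200 / 40 | cohort and subsample sizes |
| true TEE | truncated N(10.8, 2.7²) MJ/d, > 0 | reported mean and CI width |
| reporting accuracy, record | truncated N(0.80, 0.23²), > 0 | reported mean (SD) |
| reporting accuracy, ffq | truncated N(0.82, 0.33²), > 0 | reported mean (SD) |
| within-subject CV, record EI | 20.6% over d = 4 days | Goldberg inputs |
| within-subject CV, TEE | 8.4% | Goldberg inputs |
| within-subject CV, ffq EI | 0 (free parameter) | no published value |
| energy shares P/F/C/A | 0.17/0.34/0.45/0.04, log-jittered | typical Nordic adult diet |
| energy factors kJ/g | 17/37/17/29 | standard food-composition convention |
| sample days | 1, 3, 12, 14 | dosing protocol |
| dose | 1 g/kg (0.6/0.5 g/kg for BMI > 30 men/women) | dosing protocol |
| total body water | 0.50/0.58 of weight (women/men) | standard hydrometry values |
| enrichment noise | 0.5% multiplicative (log-normal) | typical IRMS precision |
| weight change | N(0, 0.3²) clipped to ±1 kg | weight-stable cohort |

Reported energy per instrument is `true TEE × accuracy × (1 + ε)` with ε
normal with SD `CV_EI/√d` (the sampling error of a d-day mean intake),
truncated above zero; macronutrient grams are back-calculated from
reported energy through per-subject shares, so energy is consistent with
the macronutrient grams under the configured factors by construction.
Truncation of the accuracy distribution at zero is > 3σ from the mean for
both instruments, so sample moments stay within 1% of the configured
values at large n.

Isotope curves are built by *inverting the engine's forward model*: pool
sizes from body weight and the total-body-water fraction (scaled by the
1.01/1.04 dilution-space conventions, giving a pool ratio of ≈ 1.03), the
rate-difference flux from the target TEE, and individual constants from a
configurable kO/kH ratio (default 1.25, yielding physiological k values
around 0.11 and 0.09 per day at 10.8 MJ/d). A noise-free cohort therefore
recovers true TEE to machine precision, which makes the round trip a
sharp correctness check on the engine rather than a statistical one.

What the generator does **not** emulate: food-item-level records and
questionnaire structure, seasonal variation, socio-economic reporting
gradients, correlated instrument errors beyond the shared true diet, and
BMI-dependent under-reporting. Passing tests therefore demonstrate the
correctness and calibration of the computational machinery under the
stated error model, not the field behaviour of any real instrument —
observed quantities that depend on the real cohort (e.g. correlation
magnitudes or κ values) are expected to differ from published ones.

## Numerical choices and degenerate inputs

Fits use closed-form OLS (numpy `polyfit`/`lstsq`-equivalent normal
equations; scipy `linregress` where a slope test is needed). Degenerate
cases fail loudly: zero energy variance (adjustment), zero EI variance
(calibration), zero-variance correlation inputs, empty or all-zero
contingency tables, < 2 usable enrichment points. Constant nutrient
series return `sqrt` with a warning (skewness undefined); constant
quantile inputs return a single bin with a warning. All-zero paired
differences return a degenerate flag with p = 1 rather than an error.

## Simulation sizes

Test and acceptance runs use the cohort sizes above plus: 100 000
subjects for the under-reporting-prevalence tail check (Monte-Carlo SE
≈ 0.0015 against a ±0.01 band), 1000 replicates for the noisy DLW
round-trip bias, 10 000 points for Bland–Altman coverage, and 10 000
datasets of n = 40 for calibration-CI coverage in the test suite (keeping
the Monte-Carlo SD of the coverage estimate ≈ 0.2%, well inside the 1%
assertion band; the acceptance script reports a 1000-dataset estimate).

## Known limitations

* The two-pool constants are one published convention; laboratories vary
  (isotope-specific space scaling, gas constants), so absolute TEE from
  real enrichment data can shift by a few percent with constant choice —
  all constants are exposed in `DlwConstants` and echoed in a JSON
  sidecar next to the results.
* The Goldberg limits here are the individual-level (n = 1) form; cohort
  screening applications with group-level terms need a different formula.
* Transformation choice is data-driven per variable; with small strata it
  can flip between log and sqrt across otherwise similar cohorts. The
  choice is recorded in the output tables.
* The FFQ within-subject CV has no published value and defaults to 0;
  sensitivity to it can be explored through the config.
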