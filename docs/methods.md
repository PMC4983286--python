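# Methods

## The estimation model

The Ekblom-Bak test exploits the near-linear within-person relationship
between heart rate and oxygen uptake during steady-state cycling. A
person with high aerobic capacity needs a smaller HR increase to absorb
a given increment in external power, so the HR rise per added watt
between two submaximal stages (ΔHR/ΔPO, bpm·W⁻¹) carries most of the
information about VO2max; unlike classical single-stage methods it does
not require an assumed maximal HR.

The revised equations are sex-specific log-linear regressions:

    ln VO2max = β0 + β1·age + β2·(ΔHR/ΔPO) + β3·ΔPO + β4·HRstd

with the published coefficients stored verbatim at their printed
5-decimal precision (`estimators.EB_NEW_COEF`). The log link keeps
estimates positive and stabilises the error variance across the fitness
range. ΔPO (the individually chosen high work rate, expressed as its
difference from the ≈30 W standard stage) and HRstd (steady-state HR on
the standard stage) enter as separate predictors; both are measured in
watts and bpm respectively — ΔPO's coefficient magnitude (~0.0018 per
unit) is only consistent with watt units, which is also the only power
unit the protocol uses. The original 2012 equation is linear in VO2max
with a 0/1 sex code; being unbounded below, its estimates can be driven
to implausible or negative values by steep HR responses, which the
package flags rather than rejects.

The shipped estimators never refit anything: `model_dev` exists to
reproduce the *procedure* (forward selection, interaction screening,
tolerance checks) on synthetic data, not to redefine the coefficients.

### Validity gating

Range checks are advisory for the regression equations (warnings and
`in_valid_range=False`): ages 20–86 y and the development cohort's
VO2max span for the sex-specific equations, ages 20–65 y and the 2012
cohort's span for the pooled one. The Åstrand nomogram's HR window
(120–170 bpm) is a hard error instead, because single-stage nomogram
readings outside it are not defined and such tests are excluded outright
in comparison studies.

### The Åstrand comparator

The nomogram estimator is fully table-driven: a long-format
(sex, work rate, HR, VO2max) grid evaluated by bilinear interpolation,
times an age-correction factor interpolated linearly between tabulated
ages. The tables shipped in `ebfit/data/` are a **synthetic
reconstruction** (so named in the filename): they are generated from the
nomogram's underlying model — linear HR extrapolation to a reference
maximal HR (195 bpm men / 198 bpm women, HR offsets 61 / 72 bpm) applied
to a standard cycling economy line (VO2 = 0.0122·W + 0.3 L·min⁻¹) —
together with the classical age-correction factors (1.00 at 25 y down
to 0.65 at 65 y). They reproduce the structure and approximate magnitude
of the published tables and support all interpolation-property tests,
but they are not a transcription; comparator conclusions about real
cohorts require plugging in a verified transcription via
`AstrandTable.from_csv`.

## Agreement statistics

All validation statistics operate on paired (measured, estimated)
VO2max values:

* **Difference sign**: estimated − measured everywhere, so positive mean
  differences mean overestimation. One constant (`agreement.DIFF_SIGN`)
  controls this.
* **CV%** = 100 × SD(differences) / mean of the two group means. Sample
  SD (n−1) is used; both the denominator reading (group means rather
  than per-pair means) and the SD convention follow standard
  method-comparison usage and are exposed as parameters.
* **SEE / adjusted R²** come from the OLS of measured on estimated
  values (SEE = residual SE with n−2 df, R² adjusted for the single
  predictor). This measures linear association, not identity — a
  perfectly proportional but biased method still scores R² = 1 — which
  is why the paired mean difference and Bland–Altman limits
  (mean ± 1.96 SD) are always reported alongside.
* **Error-vs-level**: Spearman ρ between differences and measured
  VO2max, average ranks on ties; a positive ρ with the sign convention
  above means fit individuals are overestimated less / underestimated
  more.
* **Stratification** uses sex, the age bands <35 / 35–49 / 50–64 / ≥65,
  and sex-specific quartile cut-points of measured VO2max (absolute:
  women 2.14 / 2.59 / 2.93, men 3.07 / 3.75 / 4.33 L·min⁻¹; relative:
  women 32.5 / 40.2 / 47.4, men 37.5 / 47.6 / 54.8 mL·kg⁻¹·min⁻¹).
  Cut-points are lower-inclusive: a value exactly on a boundary belongs
  to the higher quartile. Strata with fewer than 2 pairs are reported as
  NA with their count. No multiple-testing correction is applied; raw
  p-values are reported.

Statistics are implemented directly on numpy/scipy primitives; the test
suite cross-checks them against brute-force oracles (normal equations,
explicit rank sorts, closed-form t) and against statsmodels as an
independent second route.

## Model development procedure

`forward_select` implements classical probability-of-F stepwise
selection on ln VO2max: the candidate with the smallest partial-F
p-value enters while p < 0.05; after each entry, included predictors
with partial-F p > 0.10 are removed; iteration stops at a fixed point.
Software packages differ in how they phrase the entry criterion; the
partial-F p-value of the added column (equal to the squared-t p-value
for one column) is used here, and `p_enter = p_remove = 1` degenerates
to full-model OLS. Coefficient CIs are t-based with residual df.
`interaction_screen` fits the pooled two-sex model with sex ×
HR-standard and sex × (ΔHR/ΔPO) products and recommends sex-separate
fits when either partial p < 0.05 — the situation the sex-specific
equations address. Tolerance (1 − R² of each predictor on the others)
below 0.2 flags collinearity.

## The synthetic-cohort generator

Real development data are not publicly deposited, so the package is
validated on synthetic cohorts with two generation modes:

* **exact_model** draws covariates directly (age uniform 20–86 y,
  ΔHR/ΔPO uniform 0.25–1.0 bpm·W⁻¹, ΔPO uniform 60–220 W, HRstd uniform
  70–115 bpm) and sets ln VO2max exactly from a published equation plus
  optional Gaussian noise. With zero noise this creates a generative
  identity — refitting must return the printed coefficients to numerical
  precision — which is the package's primary acceptance surface.
* **physiologic** draws the phenotype first — age, body mass and VO2max
  from truncated normals matching the development cohort's sex-specific
  marginals (men 48.3 ± 15.7 y, 3.73 ± 0.86 L·min⁻¹, 80.7 ± 9.0 kg;
  women 46.1 ± 16.8 y, 2.55 ± 0.58 L·min⁻¹, 63.7 ± 8.5 kg), maximal HR
  as 208 − 0.7·age ± 8 bpm (a standard age estimator, configurable) and
  resting HR 65 ± 8 bpm (a conventional default; no cohort value is
  available) — then constructs each individual's linear HR–VO2 line from
  rest to (VO2max, HRmax), reads stage HRs off it with 3 bpm noise, and
  picks the high work rate so the on-line HR hits ≈75% of HRmax (a
  stand-in for the protocol's "perceived exertion ≈14" guidance),
  rounded to 5 W. Records violating protocol invariants are redrawn,
  capped at 1000 attempts before a hard error so infeasible
  specifications cannot silently distort the distributions.

The exact_model ln-noise SD defaults to 0.085. This is a calibration
choice, not a published residual SD: it makes a simulated 200-person
validation produce CVs near 8.5–9%, bracketing the ≈8.7% reported for
the equations on real data, so end-to-end pipeline tests run at a
realistic noise level. Problem sizes in the tests and acceptance script
(500 per sex for recovery, 200 for CV, 500 replicates for the selection
type-I check) were chosen as the smallest sizes at which the checked
quantities are statistically stable.

What passing tests show — and what they do not: the synthetic cohorts
have exactly linear HR responses, Gaussian noise and independent
covariates. Real testing adds day-to-day HR variability, medication and
caffeine effects, non-linear VO2–power behaviour near the anaerobic
threshold, and measurement error in the criterion VO2max itself, none
of which the generator emulates. Passing therefore demonstrates that
the implementation is faithful and internally consistent, not that the
equations achieve any particular accuracy in a new human population.

## Numerical choices and edge cases

* OLS via `numpy.linalg.lstsq`; rank-deficient designs raise an error
  naming the collinear columns (greedy rank-growth identification).
* Published coefficients are never re-rounded internally; reporting
  precision (2 dp L·min⁻¹, 1 dp mL·kg⁻¹·min⁻¹) is applied only at the
  output boundary.
* Zero-variance differences: paired t reports p = 1 (zero mean) or p = 0
  (nonzero mean) with a degeneracy note; Spearman ρ is reported as 0
  with a note. Constant estimated vectors make the measured-on-estimated
  regression degenerate and raise.
* `prediction_halfwidth(cv, 0)` returns 0; negative inputs raise.
* kp→watt conversion uses 6 m flywheel travel per pedal revolution
  (Monark convention, configurable) and 6.116 kpm·min⁻¹ per watt.
* Ages are accepted as decimals; outside 20–86 y a warning is emitted
  but the record is not rejected.
* Cohort CSVs are written with a fixed float format so identical
  spec + seed gives byte-identical files.

## Known limitations

* The shipped nomogram tables are synthetic (see above); Åstrand
  comparator numbers from them are structurally but not numerically
  authoritative.
* Only healthy-adult physiology is modelled; clinical populations,
  beta-blockade and other chronotropic effects are out of scope.
* The simulator does not model the criterion (treadmill) measurement
  error, so simulated agreement statistics attribute all disagreement
  to the submaximal estimate.
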