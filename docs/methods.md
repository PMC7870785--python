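# Methods

## Screening model

The package implements the classical second-trimester serum-screening
model extended to a four-analyte panel (AFP, free β-hCG, uE3, sHLA-G).
Marker levels are first standardized to multiples of the median (MoM)
of unaffected pregnancies, then log₁₀-transformed. Within each group
(unaffected, T21, T18) the log₁₀ MoM vector is treated as multivariate
Gaussian; the trisomy risk for a subject is the prior odds multiplied by
the likelihood ratio of the two class densities, mapped back to a
probability. This is the binormal likelihood-ratio framework standard in
prenatal screening, applied here with the published reference-population
parameters bundled in `serumscreen/data/default_cohort_params.json`.

Assumptions worth keeping in mind:

- **Gaussianity on the log scale.** Real marker distributions have
  heavier tails than lognormal; empirical AUCs reported for measured
  cohorts can therefore differ from what the Gaussian parameters imply.
  For the sHLA-G T18 contrast, the binormal AUC implied by the bundled
  parameters is Φ(|μ₁−μ₀|/√(σ₁²+σ₀²)) ≈ 0.879; a measured cohort with
  non-Gaussian tails can legitimately show a higher or lower empirical
  value. Quantities that depend on the unavailable patient-level data
  are out of scope here and are not asserted anywhere in the tests.
- **Correlations.** The bundled correlation matrices are Pearson
  correlations on log₁₀ MoM (the published table does not state the
  type; Pearson on the modelling scale is the coherent choice for a
  Gaussian model). The default risk computation ignores them (product
  of univariate density ratios) because they are rounded and partly
  non-significant; `use_correlations=True` switches to the full
  multivariate densities with Σ = D R D.
- **Priors.** The maternal-age risk curve used by screening labs is not
  part of the bundled data. The default is a flat prior per trisomy —
  1/5000 for T18 (newborn prevalence) and 1/700 for T21 (a conventional
  screening figure, not taken from the bundled population) — with an
  `age_table` hook for a user-supplied curve.
- **Maternal weight.** Weight enters as an optional MoM correction
  (expected MoM regressed on 1/weight among controls, observed MoM
  divided by the expectation), the standard convention. The identity
  model is the default, so unadjusted and adjusted paths are both
  available and all bundled defaults use the identity model.

## MoM engine

Medians are estimated with the lower-middle convention for even n
(the sorted element at index ⌊(n−1)/2⌋), so the control subject at the
median has MoM exactly 1 and MoM tables are bit-reproducible. AFP,
free β-hCG and uE3 use exact integer-week strata (weeks 15–19, no
interpolation); sHLA-G uses one flat overall median because it shows no
gestational trend. Fitting requires at least one control in every
requested week stratum; an empty stratum is a hard error listing the
missing weeks.

## Synthetic cohorts

The generator emulates the reference study population: group sizes
797/139/83, per-group log₁₀ MoM means, SDs and correlations, control
median sHLA-G 106.3 U/ml. Demographics are drawn as age ~ U[18, 35),
gestational week ~ uniform on {15,…,19}, and weight lognormal with
median 54.5 kg and σ(log₁₀) = 0.068, which reproduces the reported
36.8–93.0 kg range at n ≈ 800. The per-week median curves for
AFP/free β-hCG/uE3 are log-linear placeholders (their values cancel in
MoM, so they affect nothing downstream); sHLA-G uses the flat
106.3 U/ml median. Raw concentrations are reconstructed as
`10^log10MoM × median`, guaranteeing positivity and an exact round-trip
through the MoM engine (≤1e−9, in practice ~1e−16).

What the simulator deliberately does **not** emulate: assay noise and
batch effects, gestational-dating error, the heavy non-Gaussian tails of
real marker distributions, twin pregnancies and IVF conceptions, and
any dependence of demographics on group. Passing tests therefore
demonstrate the correctness of the pipeline's arithmetic and its
statistical calibration under the stated model — not the empirical
performance of any marker in a measured cohort.

If the rounded correlations ever make D R D indefinite, the covariance
is repaired by eigenvalue clipping at 1e−10 (nearest-PD) with a warning;
the three bundled matrices are positive definite as printed.

## Evaluation choices

- **ROC.** Empirical curve over all distinct cutoffs; AUC by trapezoid,
  which equals the Mann-Whitney win fraction (wins + ½·ties)/(n₁n₀)
  exactly — this identity is enforced in tests against a brute-force
  pair count, and the point estimate is cross-checked against
  scikit-learn. Reported cutoffs sit at the midpoint of adjacent
  distinct scores (one unit beyond the extremes).
- **AUC inference.** DeLong structural-components variance computed via
  midranks; 95% CI clipped to [0, 1]; p-value for AUC = 0.5 from the
  normal statistic. A normal-approximation CI would differ only in the
  variance estimate; DeLong is the default because it is distribution-
  free and handles ties.
- **Marker polarity.** Direction (`higher_is_positive` /
  `lower_is_positive`) is chosen per evaluation from the sign of the
  case-minus-control mean difference, never hardcoded; for T18 all four
  markers point down, for T21 free β-hCG and sHLA-G point up.
- **Youden cutoff.** Maximizes sensitivity + specificity − 1 over the
  ROC points; ties break toward higher sensitivity.
- **Detection rate at fixed FPR.** The cutoff is the midpoint between
  the k-th and (k+1)-th largest control scores with k = ⌊FPR·n⌋, so the
  achieved FPR is the largest step value not exceeding the target;
  fewer than 1/FPR controls is an error.
- **Confusion metrics from published rates.** Rates are converted to
  integer counts (tp = round(sens·n_case), tn = round(spec·n_ctrl))
  and every derived metric is recomputed from counts, matching how
  published screening tables are constructed.
- **Logistic regression.** statsmodels `Logit` (Newton scoring,
  tolerance 1e−8, 100 iterations cap) with Wald intervals on Exp(B).
  Perfect separation is flagged and the fit reported unconverged rather
  than raised. Covariates may be MoM or log MoM; the package does not
  assert one coding.
- **Mann-Whitney.** scipy backend: exact enumeration when the samples
  are tie-free and n_a·n_b ≤ 10,000, otherwise the tie-corrected normal
  approximation with continuity correction.
- **Degenerate inputs.** A zero-variance marker yields SD 0 with its
  correlation row/column reported as missing (NaN) rather than an
  error; building a covariance from such parameters is an error.

## Problem sizes in tests

Convergence checks use 50,000–100,000 draws per group (mean/SD within
3 standard errors, correlations within ±0.01), logistic recovery uses
n = 50,000 with 100 null replicates of n = 10,000, and property suites
run on 100 random small datasets; these sizes make the statistical
tolerances tight while keeping the full suite in the tens of seconds.

## Known limitations

- The age-risk table and the exact way measured cohorts combine the
  weight correction with the analyte LR are configurable hooks, not
  fixed conventions; results depend on those choices.
- Published group summaries are rounded to 4–5 decimals; exactly
  reproducing a measured cohort's empirical ROC/AUC values is neither
  attempted nor possible from the summary parameters alone.
- Screening thresholds (risk cutoff, target FPR) are operating-point
  choices for the user; the defaults (posterior ≥ 0.01, FPR 5%) are
  conventional, not prescriptive.
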