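# serumscreen

Second-trimester maternal serum screening for fetal trisomy 18 and
trisomy 21, built around a four-analyte panel: AFP (α-fetoprotein), free
β-hCG, uE3 (unconjugated estriol) and sHLA-G (soluble human leukocyte
antigen-G, an immunomodulatory molecule measurable in maternal serum).
The package is aimed at biostatisticians and screening-lab analysts who
want to prototype or stress-test MoM-based risk pipelines on simulated
cohorts with a realistic correlation structure.

## What it computes

1. **MoM normalization.** Each marker level is expressed as a multiple
   of the median (MoM) of unaffected pregnancies — per gestational week
   for AFP/free β-hCG/uE3, against a single flat median for sHLA-G,
   which shows no gestational trend. Modelling happens on log₁₀ MoM,
   which is close to Gaussian within each group
   (`MedianNormalizer`, a scikit-learn transformer).

2. **Gaussian likelihood-ratio risk.** Within each group *g* the
   log₁₀ MoM vector *x* is modelled as multivariate normal
   N(μ_g, Σ_g) with Σ_g = D_g R_g D_g built from per-marker SDs and
   pairwise correlations. The trisomy risk is the odds-form Bayes
   update

       LR(x) = N(x; μ_aff, Σ_aff) / N(x; μ_unaff, Σ_unaff)
       posterior odds = prior odds × LR(x)

   with the prior taken from birth prevalence (1/5000 for T18) or a
   user-supplied maternal-age table
   (`GaussianRiskClassifier`, a scikit-learn classifier).

3. **Diagnostic evaluation.** Empirical ROC curves with DeLong
   confidence intervals, Youden-index cutoffs, sensitivity/specificity/
   PPV/NPV/likelihood-ratio tables, detection rate at a fixed
   false-positive rate, and multivariate logistic regression with Wald
   odds-ratio intervals.

4. **Synthetic cohorts.** Because the underlying patient-level study
   data are available only on request, `serumscreen.datasets` simulates
   cohorts with the published population structure (797 controls, 139
   T21, 83 T18; group-specific log₁₀ MoM means, SDs and correlations;
   maternal age 18–35, weight median 54.5 kg, weeks 15–19), fully
   reproducible from a single seed.

## Worked example

```python
import numpy as np
import serumscreen as ss

params = ss.load_default_params()          # per-group Gaussian parameters
clf = ss.GaussianRiskClassifier.from_group_params(
    params["T18"], params["control"], prior=1/5000
)

# a pregnancy with low AFP, very low free beta-hCG, low uE3, low sHLA-G
profile = np.log10([0.60, 0.25, 0.55, 0.40])   # MoM, panel order
lr = clf.likelihood_ratio(profile.reshape(1, -1))[0]
post = clf.predict_proba(profile.reshape(1, -1))[0, 1]
print(f"likelihood ratio = {lr:.1f}")
print(f"posterior risk   = {post:.4f}  (~1 in {round(1/post)})")
```

prints

```
likelihood ratio = 51.0
posterior risk   = 0.0101  (~1 in 99)
```

that is, this marker profile is 51 times more likely under the T18 model
than under the unaffected model, lifting the 1-in-5000 prior to roughly
1-in-99 — far beyond a typical 1-in-250 referral threshold.

Confusion-table arithmetic from published operating points:

```python
m = ss.metrics_from_rates(0.855, 0.887, n_case=83, n_ctrl=797)
print(f"PPV {m.ppv:.1%}  NPV {m.npv:.1%}  PLR {m.plr:.2f}  NLR {m.nlr:.2f}")
# PPV 44.1%  NPV 98.3%  PLR 7.58  NLR 0.16
```

The full pipeline (simulate → MoM → risk → evaluate → CSV reports) runs
from the command line:

```sh
serumscreen run-all --seed 1 --out screening_run
```

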