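# regimecox

Treatment-specific marginal structural Cox models (MSMs) for the causal
effect of **treatment discontinuation** on a survival endpoint, estimated
with **inverse-probability-of-regime-compliance (IPRC) weights**.

## The problem

Patients initiated on one of two treatments (think of the two oral
anticoagulant classes given to atrial-fibrillation patients) often
discontinue their medication.  Asking what discontinuation *causes* — on
the hazard of death, stroke, or another failure event — runs into three
entangled biases:

1. **treatment confounding** — initial treatment is not randomized;
2. **regime confounding** — time-dependent covariates (e.g. bleeding
   events) both predict future discontinuation and are affected by past
   discontinuation, so a standard time-dependent Cox adjustment is biased;
3. **informative artificial censoring** — subjects who switch treatments
   or restart after discontinuing are inconsistent with every regime
   "take treatment *a*, discontinue at ν" and must be censored at their
   violation time, an act that is itself informative.

`regimecox` fits the treatment-specific MSM

λ<sub>aν</sub>(t) = λ<sub>00</sub>(t) · exp(β₁\* a + β₂\* z<sub>ν</sub>(t) + β₃\* a z<sub>ν</sub>(t)),  z<sub>ν</sub>(t) = 1(ν ≤ t),

by weighted Cox partial likelihood, where the subject- and time-specific
IPRC weight is the product of a treatment-propensity component, an
artificial-censoring component, and a discontinuation component (see
`docs/methods.md` for the full construction).  β<sub>a</sub> = β₂\* + β₃\*·a
is the causal log hazard ratio of discontinuing versus never discontinuing
in arm *a*; β₃\* = 0 is the test of effect modification by treatment.

The package provides:

* `survdata` — counting-process (start–stop) tables, CSV I/O, interval
  construction from subject-level times, artificial censoring;
* `coxtv` — a fast weighted time-dependent Cox engine (Breslow baseline,
  clustered sandwich variance, per-subject survival prediction);
* `nuisance` — propensity, regime-violation and (weighted)
  discontinuation hazard models, fitted in the order the weights require;
* `weights` — IPRC weight assembly, truncation, diagnostics;
* `msm` — interaction / constant / time-varying-effect MSM fits, Wald
  tests, subject-level bootstrap;
* `simulate` — the piecewise-exponential data-generating process used to
  validate the estimator, plus counterfactual cohorts;
* `harness` — Monte-Carlo comparison of the MSM against two naive
  time-dependent Cox estimators, with a `regimecox` CLI.

## Worked example

```python
import numpy as np
from regimecox import DGPConfig, draw_cohort, msm_pipeline, fit_naive1

cohort = draw_cohort(DGPConfig(n=1000, seed=1, beta=(0.0, 0.0, 0.0)))

naive = fit_naive1(cohort.tbl_full)       # ignores regime violation
causal = msm_pipeline(cohort)             # IPRC-weighted MSM
print("naive:", np.round(naive.coef, 3))
print("msm  :", np.round(causal.coef, 3))
print("msm robust SE:", np.round(causal.robust_se, 3))
```

prints

```
naive: [-1.465 -0.366  0.7  ]
msm  : [ 0.178 -0.034 -0.25 ]
msm robust SE: [0.195 0.168 0.231]
```

The cohort was simulated with **no** treatment or discontinuation effect
(β\* = 0).  The naive time-dependent Cox fit is wildly biased — subjects
who violate the regime keep their (violation-affected) failure times, so
it reports a spurious protective treatment effect of β̂₁ ≈ −1.47.  The
IPRC-weighted MSM recovers estimates within one robust standard error of
the true zeros.  Replicated over many cohorts (`regimecox
replicate-study`), the naive means stay near (−1.47, −0.30, 0.78) while
the MSM means converge to the truth with ~95% Wald coverage.

The same pipeline runs on your own data from CSV:

```python
from regimecox import read_table
from regimecox.harness import msm_pipeline_from_table

tbl = read_table("cohort_regime.csv")      # id,start,stop,event,treat,zv,q*,x*
res = msm_pipeline_from_table(tbl, gamma_s, truncation=100,
                              specs=dict(propensity_spec=("xage", "xsex"),
                                         disc_denom_spec=("treat", "qbleed")))
print(res.coefficient_table())
```

where `gamma_s` flags, per subject, whether follow-up ended by regime
violation, and `truncation` caps unstable weights (sensitivity grid
50/100/150).

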