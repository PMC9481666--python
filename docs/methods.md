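# Methods

## The estimand and the model

`regimecox` estimates the causal effect of *treatment discontinuation* on a
survival endpoint in a two-arm observational cohort.  The intervention is a
fixed, treatment-specific regime "take treatment `a` until discontinuing it
at time ν" (ν = ∞ means never discontinue).  Writing `T^{aν}` for the
potential failure time under that regime and `z_ν(t) = 1(ν ≤ t)`, the
marginal structural Cox model (MSM) is

    λ_{aν}(t) = λ_00(t) exp(β1* a + β2* z_ν(t) + β3* a z_ν(t)),

so `β_a = β2* + β3* a` is the log hazard ratio of "discontinued" versus
"never discontinued" follow-up within arm `a`, and `β3*` quantifies
treatment-by-discontinuation effect modification.  The package also fits the
constant-effect model (no interaction) and a time-varying-effect variant
with an extra `βTD* (t − ν) z_ν(t)` term, under which the effect of
discontinuation depends on the time since discontinuation.

A subject can become inconsistent with *every* regime `(a, ν)` — by
switching treatments, or restarting one after discontinuing ("regime
violation", at time `R`).  Such subjects are artificially censored at
`S = min(R, U)`, where `U = min(T, C)` ends regular follow-up.  Artificial
censoring is potentially informative, and the time-dependent covariates that
predict discontinuation may themselves be affected by earlier
discontinuation ("regime confounding").  Both problems, plus ordinary
treatment confounding, are handled by a single set of subject- and
time-specific inverse-probability-of-regime-compliance (IPRC) weights.

## The IPRC weights

For arm `a`, subject `i`, time `t`, the weight is the product of three
components (exactly one "line" is active at any `(i, t)`; the weight is 0
when `A_i ≠ a` or `t > S_i`):

1. **Treatment**: `1(A_i = a) / π_A(X_i)`, with `π_A(X) = A π(X) +
   (1−A)(1−π(X))` from a logistic propensity model.  An optional marginal
   numerator `pr(A = a)` stabilizes this component; the default leaves it
   unstabilized (the two differ by a constant factor, which the weighted
   partial likelihood ignores).
2. **Artificial censoring**: `1(S_i ≥ t) · K_R(t | X, A) / K_R(t | H̄(t),
   Z_V(t))`, the stabilized inverse probability of remaining
   regime-compliant.  The denominator comes from a time-dependent Cox model
   for the violation hazard given the full history; the numerator from a
   Cox model given baseline covariates and treatment only.
3. **Discontinuation** (regime confounding), branching on status at `t`:
   - not yet discontinued (`t ≤ V_i`): `K_D(t | X, A) / K_D(t | H̄(t))`;
   - discontinued at `V_i < t`: the ratio of numerator to denominator
     *hazard-increment-times-survival* at `V_i`, constant afterwards.  Both
     discontinuation hazards are represented through their Breslow
     increments, so the infinitesimal `dt` and the baseline jump masses
     cancel in the ratio and no hazard smoothing is ever needed.

The discontinuation *denominator* model must itself be weighted: its risk
sets end at regime violation, so it is fitted with the compliance weights
`ω_D(t) = 1(S ≥ t) K_R(t|X,A) / K_R(t|H̄,Z_V)` built from the violation
models.  The workflow order (propensity → violation models → `ω_D` →
weighted discontinuation model → numerator models → weight assembly →
weighted MSM fit) is enforced programmatically: the weighted
discontinuation fit refuses weights that did not come from the violation
step.

### Weight evaluation grid

Weights are piecewise constant and left-continuous.  The weighted
estimating equations only read `ω_i(t)` at failure event times, over the
subjects then at risk.  The analysis table is therefore split at all
failure event times and the weight is evaluated at each sub-interval's
right endpoint with left-continuous survival evaluations (`K(t−)`): this
representation is exact at every point the estimator uses.  Subject-level
boundaries (covariate changes, `V_i`, `S_i`) are interval edges already.
Adding the nuisance models' own event times as further change points would
change no fitted quantity and inflate the table roughly tenfold, so it is
not done.

### Truncation

Products of three inverse-probability components can be unstable when a
denominator approaches zero.  `weights.truncate` caps weights (the
conventional sensitivity grid is 50 / 100 / 150) and reports how many
subject-intervals were affected; the simulation harness applies no
truncation by default because the simulated weights are well behaved.

## The weighted Cox engine

`coxtv.fit_cox` maximizes the case-weighted Cox partial likelihood on
counting-process data by Newton–Raphson with step-halving, Breslow tie
handling, and convergence when the maximum coefficient change falls below
1e-9 (or the relative log-likelihood change below 1e-12; at most 100
iterations).  Intervals are half-open `(start, stop]`; covariates and
weights are left-continuous step functions, so all processes entering the
risk sets are predictable.  Risk-set sums at all event times are computed
with prefix sums over rows sorted by `stop` and by `start` (membership
`start < t ≤ stop` is a difference of two prefix sums), giving
O((rows + events) log rows) iterations; this is what makes thousands of
Monte-Carlo replicates practical.

Weights enter score and information as case weights with no
re-normalization — the estimating-equation form of inverse-probability
weighting.  The default variance is the clustered sandwich `A⁻¹ B A⁻¹`
with score residuals summed within subject before the outer product, which
remains valid when one subject contributes many weighted intervals; 95%
intervals are Wald intervals on these robust SEs.  The nonparametric
bootstrap over subjects (`msm.bootstrap_ci`) is available as an
alternative but is not the default (it reruns the entire
nuisance-plus-weighting pipeline per draw).  Monotone likelihood
(divergent coefficients from degenerate risk sets) is *flagged* on the
returned fit rather than raised, so replicated simulations survive rare
degenerate cohorts and report them; a singular information matrix raises,
naming the (nearly) collinear columns.

Ties: the simulator produces continuous times, so ties have probability
zero; Breslow handling matches the Breslow baseline estimator used for all
survival predictions.  Exact ties among a subject's latent times are broken
with the fixed priority `T < C < R < D`.

## The synthetic-data generator

`simulate.draw_cohort` reproduces the study conditions used to validate
the estimator.  Per subject: treatment `A ~ Bernoulli(0.5)`; a frailty
`G ~ Exp(rate 0.2)`; a time-dependent covariate measured at t = 0, 5, 10,
`(Q(0), Q(5), Q(10)) ~ N(0.2·G − 4, Σ)`, `Σ_ij = 0.7^|i−j|`, constant
between measurements.  Latent times follow piecewise-exponential
proportional-hazards models (natural logs, rates per unit time):

| time | hazard |
|---|---|
| discontinuation `D` | `0.15 exp(0.15 A + 0.15 Q(t))` |
| regime violation `R` | `0.15 exp(0.15 A + 0.15 (1−Z_V(t)))` |
| failure `T` | `0.15 exp(β1* A + β2*(1−Z_V(t)) + β3* A(1−Z_V(t)) + 0.1 Q(0))` |
| censoring `C` | `0.025 exp(0.15 A + 0.15 (1−Z_V(t)))` |

After `D` is drawn, measurements at times `l > D` are updated to
`Q(l) + log(l − D)` — this is the regime-confounding loop (exposure →
covariate → future exposure and outcome).  The update is applied only at
the measurement times 5 and 10, where `Q` is defined, and is implemented
exactly as stated even when `l − D < 1` (large negative shift).  Whenever
`R < T` and `A = 1`, `T` is multiplied by 5, so regime violation affects
the failure time in one arm — this is what makes naive analyses that ignore
violation badly biased.  Under this scheme the MSM holds with the
*on-treatment* coding `d(t) = 1 − z_ν(t)`; the fitting code supports both
codings (they are reparameterizations: flipping the coding negates β2* and
β3* and shifts β1* by β3*).

Sampling inverts the piecewise-constant cumulative hazard exactly (no
discretization).  Randomness uses one counter-based Philox stream per
replicate, keyed by `(seed, replicate)`, with all subject-level draws as
fixed-order vectorized columns — every cohort is bit-reproducible
independently of execution order.

`simulate_counterfactual` draws potential failure times under a forced
regime (fixed `a` and ν, violation and censoring disabled, no multiplier)
and serves as the oracle for the causal contrasts in the tests.

What the generator does **not** emulate: real registries have
administrative censoring horizons, covariate measurement at irregular
visit times, many correlated covariates, missingness, and discrete (daily)
time grids.  Passing tests therefore demonstrate correctness of the
estimator under a known, continuous-time, correctly specified
data-generating process — not robustness to misspecification, which the
study conditions deliberately do not probe.

## The Monte-Carlo harness

`harness.run_replications` compares three estimators at a given `β*`:
Naive 1 (unweighted time-dependent Cox on `A`, `1−Z_V(t)`, interaction),
Naive 2 (Naive 1 plus `Q(t)`), and the full MSM pipeline.  The naive fits
use follow-up censored only at `C` — they ignore regime violation
entirely, so `A = 1` violators retain their five-fold-inflated failure
times; only the MSM pipeline censors at `R`.  (This reading is the one
consistent with the large published naive biases; it is toggleable by
fitting the naive models on the regime-censored table instead.)  Default
nuisance specifications mirror the data-generating hazards: propensity on
`Q(0)`; violation denominator on `(A, 1−Z_V)`; discontinuation denominator
on `(A, Q(t))`; both stabilizing numerators on `A` alone.  Coverage is the
fraction of replicates whose 95% robust-SE Wald interval (z = 1.959964)
contains the truth.

## Problem sizes and numerical choices

* Test-suite replication runs use B = 200 replicates per setting (cohorts
  of n = 1000) with Monte-Carlo tolerances of 3·SD/√B; the acceptance
  script uses B = 250.  Full-scale runs (B = 2000) are available through
  `replicate-study -B 2000`.
* Nuisance parameter-recovery checks run at n = 4000 with 3-SE
  tolerances (the criterion is sample-size adaptive).
* The linear predictor is clipped at ±500 before exponentiation (overflow
  guard; reached only on divergent monotone-likelihood paths).
* `hazard_increments` returns 0 at non-event times; survival predictions
  are right-continuous step functions starting at 1.
* Positivity failures (zero denominator survival or hazard increment at an
  at-risk time, propensity at 0 or 1) raise a dedicated error naming the
  subject and time rather than producing infinite weights.

## Known limitations

* No competing-risks event-specific MSMs and no informative-censoring
  weighting: under the package's assumptions censoring is non-informative.
  If that fails, `R` can be redefined as "violation or censoring,
  whichever first" and the same machinery reused with a richer violation
  model — the hook exists because the violation model specification is
  free, but no dedicated interface is provided.
* No penalized (LASSO) nuisance fitting, no Efron ties, no stratification,
  no left truncation beyond `start > 0` rows, no recurrent events.
* Bonferroni correction for multiple endpoints is a reporting utility
  (`MSMResult.bonferroni`), not applied by default.
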