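# Methods

`seqbenefit` estimates, for every patient on a waiting list and for every
calendar date at which a scarce treatment becomes available, the
conditional survival benefit of accepting that specific treatment now
versus never being treated, over a fixed horizon of L = 3 years.  This
note records the model, the synthetic data-generating mechanism, the
numerical choices, and what the shipped tests do and do not establish.

## Estimands and model

At cross-section date `CS_k`, let `S_k` be a patient's time since first
eligibility and `u = t − S_k` the reset clock.  The two potential residual
survival curves for an eligible patient are `S0(u, S_k | Z̄_k)` ("never
treat") and `S1,ℓ(u, S_k | Z̄_k)` ("treat now with offer ℓ"), and the
estimands are their restricted mean survival times (RMST, the area under
the curve up to L) and the benefit `dℓ = RMST1,ℓ − RMST0`.  Under
consistency, positivity and sequential conditional exchangeability these
are identified from observational data by artificially censoring subjects
when they deviate from a strategy and reweighting by the inverse
probability of adherence.

Both arms are modeled as weighted Cox proportional-hazards models on the
reset clock:

    λ0,k(u | Z_k)        = λ00(u) · exp(β0' Z_k)
    λ1,k,ℓ(u | Z_k, Z*)  = λ01(u) · exp(β1' (Z_k, Z*))

with `Z*` the offer's treatment-specific covariates (multiple versions of
treatment).  The baseline hazards are pooled across cross-sections by
default (`MSMOptions.baseline="pooled"`, the choice also natural for
prediction at new dates); per-cross-section baselines are available.  The
two arms can be fitted separately (default) or as one jointly stratified
model with arm-specific covariate effects; the two are equivalent when the
joint model is fully interacted, and the test suite asserts this.

### Stabilized weights

Never-treated-arm records at cross-section k receive the time-varying
weight

    W_k(u) = exp(−Λ0,num,k(u | Z_k)) / exp(−Λ0,den(S_k, S_k+u | Z̄))

where the denominator is a Cox model for time-to-treatment on the original
follow-up scale with the time-varying covariate history, and the numerator
(the stabilizer g(Z_k)) is a Cox model from each cross-section with
covariates frozen at `Z_k`, one baseline per cross-section, shared
coefficients.  Treated-arm records receive the time-constant weight

    W_k = λ1,num / P̂(offer receipt | Z_k, Z*, interactions)

with `P̂` from a complementary log-log regression with a single pooled
intercept (treatments are scarce: few recipients per date) and `λ1,num`
the pooled empirical per-offer treatment probability.  Weights can be
truncated at a quantile of the pooled weight distribution
(`cap_quantile`); registry-style analyses conventionally use 0.9999, the
simulation study runs uncapped.

All partial-likelihood fits (weight models, outcome models, comparators)
use one internal counting-process engine with Breslow tie handling and a
weighted Breslow baseline, Newton iteration with step halving, optional
strata (folded into a single vectorized pass by translating each stratum
onto a disjoint time segment), and clustered sandwich standard errors via
score residuals.  The engine is cross-checked in the tests against
lifelines (coefficients, baselines, robust SEs, start–stop data) and
against brute-force 1-D likelihood maximization.

## Synthetic data-generating mechanism

The generator emulates a transplant-style waiting list observed for 10
calendar years.  Defaults (all per the study design the package
replicates):

| parameter | default | meaning |
|---|---|---|
| `window_end` | 10 y | calendar observation window |
| `horizon_L` | 3 y | RMST horizon |
| `mu_sd`, `eta_sd` | 1, 0.5 | patient level and drift of Z(t) = μ + ηt + ξ(t) |
| `ou_theta`, `ou_sigma` | 0.1, 0.0045 | OU mean reversion and diffusion of ξ |
| `ou_burnin_steps` | 100 | burn-in updates from 0 at step `grid_dt` |
| `lambda0_slope`, `beta0_true` | 0.2, 1.5 | untreated death hazard 0.2 t · e^{1.5 Z(t)} |
| `lambdaT_slope`, `betaT_true` | 0.25, 2 | treatment hazard 0.25 t · e^{2 Z(t)} |
| `lambda1_slope`, `gamma1_true` | 0.075, 1 | post-treatment hazard 0.075 v · e^{f(Z(T)) + Z*} |
| `f_breakpoints/plateaus/slope` | ±0.6, ±1.2, −2 | piecewise-linear effect of health at treatment |
| `eligibility_threshold` | −1 | cross-section inclusion requires Z > −1 |
| `cs_spacing_coarse/fine` | 0.04 / 0.01 y | date grids on [0, 9) |
| `grid_dt` | 0.01 y | covariate/time grid step |

The OU fluctuation is advanced with its exact Gaussian transition (no
discretization bias at any step size); burn-in uses step `grid_dt`.  Event
times are drawn by inverse-transform sampling with the cumulative hazard
accumulated exactly within each grid cell (linear baselines integrate to
quadratics), so draws are continuous; matching of treatment times to
cross-section dates rounds to the nearest fine date, ties toward the
earlier date.  `X = min(D0, T, window_end − s_entry)` decides the observed
episode; a latent T ≥ D0 is discarded.  Each fine date carries an offer
quality Z* ~ N(0,1); dates at which an observed treatment occurred carry
that treatment's Z*, several treatments on one date become separate
cross-sections.

Ground truth for a (patient, cross-section) pair integrates the patient's
own hazard along their realized covariate path:
`RMST0 = ∫0^L exp(−∫_{S_k}^{S_k+u} h0(s|Z(s)) ds) du` (inner integral
exact per grid cell, outer trapezoid on the 0.01-y grid; halving the step
changes results by < 1e-4) and
`RMST1 = ∫0^L exp(−0.0375 u² e^{f(Z_k)+Z*}) du`.  The truth conditions on
the realized future covariate path; the calibration smoother (below)
performs the marginalization over future paths implicitly.

### Eligibility semantics

The fitness rule `Z > −1` is a proxy for removal-due-to-improvement and is
applied only as the cross-section inclusion predicate for the
never-treated arm (the waiting-list estimand population); it does not gate
the latent treatment process, and re-entry at later dates is possible.
Two consequences, adopted deliberately after analysis of the alternative:

* an actual recipient of an offer is eligible at their own cross-section
  by definition (receiving treatment implies availability), so treated-arm
  rows are never dropped by the fitness proxy (a below-threshold count is
  reported in provenance);
* the receipt-probability model's risk set defaults to all alive,
  untreated, uncensored patients (`offer_risk_set="at_risk"`), matching
  the process that actually selects recipients.  Fitting it on a
  threshold-truncated risk set while recipients bypass the threshold would
  inject a spurious covariate effect (≈ −1.5 under a null design where the
  true effect is 0).  With registry data carrying an authoritative
  eligibility column, that column gates as given.

## Comparator methods

* **naive** — unadjusted Cox fits from a single time origin: entry (with
  Z(0)) for never-treated mortality, treatment time (with Z(T) and Z*) for
  post-treatment mortality.  Residual predictions at `S_k` condition the
  fitted curve on survival to `S_k`.  The post-treatment model includes
  Z*; without it there would be no version-specific RMST1 to rank offers
  by.
* **cs_unweighted** — the identical cross-section pipeline with all
  weights set to 1.

Both expose the same prediction interface as the weighted fit.

## Evaluation

Per replication, the three methods are fitted and evaluated at every
eligible (patient, coarse cross-section) point; points are pooled across
replications.  The calibration curve is a lowess (local linear) smooth of
truth on estimate, span 0.75, fitted on at most 20 000 points (seeded
subsample) and interpolated onto the full cloud; RMS bias is the root mean
squared distance between the smooth and the diagonal over the points,
after trimming estimates outside their 1st–99th percentiles (smoother
boundary artifacts).  The study sizes shipped with the package are 50
replications × 1000 patients for the method-ordering analysis and a
20 × 500 smoke variant in the acceptance script; both reproduce the same
qualitative ordering (weighted best for RMST0 and benefit; the two
unadjusted methods nearly identical for RMST1).

### Weight-update resolution

Time-varying weights are step functions whose jumps are the Breslow
baselines' event times.  Expanding every row at every jump is exact but
quadratic in cohort size; instead rows are expanded on a fixed weight-
update grid (`weight_update_step`, default 0.04 y = the coarse date
spacing) with both cumulative hazards evaluated at interval right
endpoints.  The weighted partial likelihood only consumes weights at death
times, so the approximation error is the within-cell drift of the weight,
second-order at this resolution.

### Designed variants used by the tests

* `linear_variant_config` — f replaced by −2x everywhere.  The treated-arm
  model is then correctly specified and recovers (−2, 1); the
  never-treated marginal model remains misspecified (Z drifts after S_k),
  so its coefficient is attenuated relative to 1.5 — this is a property of
  the estimand, not an estimator defect.
* `proportional_variant_config` — additionally freezes Z in time and makes
  the death baseline a constant rate, so the never-treated reset-clock
  model holds exactly (coefficient 1.5 recovered; pooled calibration
  slopes ≈ 1).  Confounding is retained, so the weights still have work to
  do.
* `null_confounding_config` — treatment independent of Z, constant
  baselines, frozen covariates, linear f: every fitted model is correctly
  specified and there is nothing to adjust for.  All stabilized weights
  are 1 up to sampling noise and the three methods agree.  Tolerances in
  the tests (weight quantiles within [0.7, 1.4], mean within 5% of 1,
  RMS prediction differences < 0.2 y) were set at roughly twice the noise
  observed in pilot runs with seeds disjoint from the test seeds, at
  n = 2000.  Mean-weight-per-decile contracts are assessed against the
  Monte Carlo standard deviation of the per-run decile mean across
  replications at n = 3200 — the sampling unit at which that statistic
  varies.  Within-run row-level SEs ignore the shared estimation noise of
  the fitted cumulative hazards and overstate precision by an order of
  magnitude; and exponentiating estimated cumulative hazards carries a
  small positive O(1/n) finite-sample bias (E[e^X] = e^{Var/2} for the
  estimation noise X), visible as mean weights up to ~1% above 1 at late
  follow-up, shrinking with cohort size.

## Numerical choices and degenerate inputs

* Breslow ties everywhere (consistent with the Breslow baselines the
  weights integrate); counting-process intervals are half-open `(start,
  stop]`; a subject whose event time equals a cross-section date counts as
  a post-date outcome ("just before" eligibility).
* Strata with no events get flat baselines and are flagged; complete
  separation in the cloglog model triggers a ridge-stabilized refit with a
  warning; a predicted receipt probability of 0 for a treated row raises a
  positivity error naming the row.
* RMST integrals of fitted step survival functions are exact sums of step
  heights × widths, clipped at L.
* CSV output uses `%.17g` and reading uses round-trip float parsing, so
  tables survive write/read bit-exactly; application-style output can be
  rounded to 0.01 y with a switch.
* Replication seeds are spawned from a single root seed (`SeedSequence`);
  identical seeds reproduce populations bit-identically.

## What the tests show, and what they do not

The synthetic generator has one patient covariate, one offer covariate,
administrative censoring only, and exchangeability holds by construction.
Passing tests therefore demonstrate internal correctness (estimators
recover what the design says they should, weights satisfy their
contracts, the method ordering replicates) — not robustness to
unmeasured confounding, informative censoring, measurement error, or
high-dimensional covariates in real registry data.  Conditionally
independent censoring is assumed throughout; reweighting for informative
censoring is out of scope.  Only the strategies "never treat" and "treat
now with this offer" are implemented; "treat later" strategies are not.
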