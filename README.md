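# seqbenefit

Sequential cross-section marginal structural models for estimating the
**conditional survival benefit** of a scarce treatment — the expected
life-years (within a 3-year horizon) a patient would gain by receiving the
treatment offer available *now* rather than never being treated — for every
patient on a waiting list, at every calendar date an offer arrives.

The motivating setting is deceased-donor liver transplantation: organs
arrive irregularly, differ in quality, and are currently allocated
"sickest first" (by MELD score). A benefit-based policy instead ranks the
waiting list by each patient's expected gain from *this* organ *today*.
Estimating that gain from registry data faces three obstacles: treatment
assignment is confounded by time-varying health markers that treatment
itself affects; decisions happen in calendar time while survival is
comparable on time-since-listing; and "treated" is many treatments (organ
quality varies).

## Method

At every calendar date `CS_k` a treatment becomes available, the eligible
waiting list forms a trial-like cohort with reset clock `u = t − S_k`.
Stacking these cohorts, two weighted Cox models estimate the potential
outcomes under "never treat" and "treat now with offer ℓ":

```
λ0,k(u | Z_k)       = λ00(u) exp(β0' Z_k)                (never treated)
λ1,k,ℓ(u | Z_k, Z*) = λ01(u) exp(β1' (Z_k, Z*))          (treated at k)
```

Records are artificially censored when they deviate from a strategy and
reweighted by stabilized inverse-probability-of-treatment weights built
from three fitted components: a time-varying Cox model for remaining
untreated, a per-cross-section stabilizer with frozen covariates, and a
complementary log-log model for receiving the specific offer. Predictions
compose the weighted Breslow baselines with the linear predictors:

```
RMST0 = ∫0^L exp(−Λ00(u) e^{β0'Z_k}) du
RMST1 = ∫0^L exp(−Λ01(u) e^{β1'(Z_k,Z*)}) du
dℓ    = RMST1 − RMST0        (the conditional survival benefit)
```

The package ships the full estimation pipeline, two comparator methods
(naive single-origin Cox models; the same cross-section pipeline without
weights), a synthetic waiting-list generator with exact ground-truth
RMSTs, and a replicated calibration study. See `docs/methods.md` for the
model, assumptions, and numerical choices.

## Worked example

```python
from seqbenefit import DGMConfig, RunConfig, generate_population
from seqbenefit.msm import predict_benefit
from seqbenefit.pipeline import build_stacks, evaluation_points, fit_method

cfg = RunConfig(dgm=DGMConfig(n_patients=1000, seed=7))
pop = generate_population(cfg.dgm)
stacks = build_stacks(pop, cfg)
fit = fit_method(pop, cfg, "cs_weighted", stacks)

pts = evaluation_points(pop, stacks)
date_rows = pts[pts["k"] == pts["k"].mode()[0]]
ranking = predict_benefit(fit, date_rows, {"Zstar": float(date_rows["Zstar"].iloc[0])})
print(ranking.head())
```

prints (`examples/estimate_benefit.py`):

```
cross-section 147 (calendar 5.88, offer Z* = 0.44): 140 eligible patients
 patient_id   k    Sk  rmst0_hat  rmst1_hat  benefit_hat  rank
        749 147 0.414      0.435      2.887        2.452     1
        768 147 0.743      0.654      2.838        2.184     2
        866 147 0.236      0.710      2.826        2.116     3
```

Patient 749 is expected to live 0.44 of the next 3 years without a
transplant but 2.89 years with this particular offer — a benefit of 2.45
life-years, putting them first in a benefit-based allocation. A small
replicated study (`examples/replicate_calibration.py`, 5 × 400 patients)
reproduces the method comparison:

```
estimand       benefit  rmst0  rmst1
cs_unweighted    0.214  0.192  0.105
cs_weighted      0.164  0.042  0.107
naive            0.338  0.482  0.102
```

— root-mean-squared calibration bias (years): the weighted cross-section
method is markedly better calibrated for the never-treated RMST and the
benefit, while the two unadjusted methods are nearly interchangeable for
the post-treatment RMST, whose fit is not confounded in the same way.

A thin CLI wraps the same pipeline: `seqbenefit simulate|fit|predict|evaluate --help`.

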