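"""Configuration objects for the simulation and estimation pipeline.

All time quantities are in years.  The data-generating mechanism emulates a
transplant-style waiting list observed over a 10-year calendar window: one
time-dependent health covariate Z(t) per patient (linear drift plus a
mean-zero Ornstein-Uhlenbeck fluctuation), hazards for untreated death and
for receiving treatment that both increase log-linearly in Z(t), and a
post-treatment death hazard driven by health at treatment Z(T) and by a
treatment-quality covariate Z*.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator


class DGMConfig(BaseModel):
    """Parameters of the data-generating mechanism.

    Defaults reproduce the simulation design verbatim: observational window
    of 10 calendar years, 3-year horizon, OU covariate fluctuation with
    mean-reversion theta = 0.1 and diffusion sigma = 0.0045, untreated death
    hazard 0.2 t exp(1.5 Z(t)), treatment hazard 0.25 t exp(2 Z(t)),
    post-treatment hazard 0.075 v exp(f(Z(T)) + Z*) with f a decreasing
    piecewise-linear function plateauing at +/-1.2 outside (-0.6, 0.6).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    window_end: float = 10.0
    horizon_L: float = 3.0
    grid_dt: float = 0.01
    n_patients: int = 2500
    ou_theta: float = 0.1
    ou_sigma: float = 0.0045
    ou_burnin_steps: int = 100
    mu_sd: float = 1.0
    eta_sd: float = 0.5
    lambda0_slope: float = 0.2
    #: if set, the untreated-death baseline hazard is this constant rate
    #: instead of ``lambda0_slope * t`` (proportional-hazards variants)
    lambda0_constant: Optional[float] = None
    beta0_true: float = 1.5
    lambdaT_slope: float = 0.25
    #: if set, the treatment baseline hazard is this constant rate instead of
    #: ``lambdaT_slope * t`` (used by the fully null design; see methods note)
    lambdaT_constant: Optional[float] = None
    betaT_true: float = 2.0
    lambda1_slope: float = 0.075
    gamma1_true: float = 1.0
    f_breakpoints: tuple[float, float] = (-0.6, 0.6)
    f_plateaus: tuple[float, float] = (1.2, -1.2)
    f_slope: float = -2.0
    #: replace the piecewise f by the linear map f_slope * x everywhere
    f_linear: bool = False
    eligibility_threshold: float = -1.0
    cs_spacing_coarse: float = 0.04
    cs_spacing_fine: float = 0.01
    cs_calendar_end: float = 9.0
    seed: int = 0

    @property
    def t_max(self) -> float:
        return self.window_end + self.horizon_L

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.t_max / self.grid_dt))
        return np.linspace(0.0, n * self.grid_dt, n + 1)

    @model_validator(mode="after")
    def _check(self):
        for name in (
            "window_end",
            "horizon_L",
            "grid_dt",
            "ou_theta",
            "lambda0_slope",
            "lambdaT_slope",
            "lambda1_slope",
            "cs_spacing_coarse",
            "cs_spacing_fine",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.ou_sigma < 0 or self.mu_sd < 0 or self.eta_sd < 0:
            raise ValueError("scale parameters must be >= 0")
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        ratio = self.cs_spacing_coarse / self.cs_spacing_fine
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("cs_spacing_fine must divide cs_spacing_coarse")
        if self.grid_dt > self.cs_spacing_fine + 1e-12:
            raise ValueError("grid_dt must not exceed cs_spacing_fine")
        return self

    def f_effect(self, x) -> np.ndarray:
        """Effect of health at treatment on the post-treatment log-hazard."""
        x = np.asarray(x, dtype=float)
        if self.f_linear:
            return self.f_slope * x
        lo, hi = self.f_breakpoints
        plo, phi = self.f_plateaus
        return np.where(x <= lo, plo, np.where(x >= hi, phi, self.f_slope * x))

    def dates_coarse(self) -> np.ndarray:
        n = int(np.ceil(self.cs_calendar_end / self.cs_spacing_coarse - 1e-9))
        return np.arange(n) * self.cs_spacing_coarse

    def dates_fine(self) -> np.ndarray:
        n = int(np.ceil(self.cs_calendar_end / self.cs_spacing_fine - 1e-9))
        return np.arange(n) * self.cs_spacing_fine


def null_confounding_config(base: DGMConfig | None = None, **overrides) -> DGMConfig:
    """The package's canonical no-confounding design.

    Treatment is made independent of the covariate (betaT = 0) with
    time-constant treatment and death baselines, the covariate is frozen in
    time (no drift, no OU fluctuation, so Z(0) = Z(Sk) = mu) and the
    post-treatment covariate effect is linear.  Under this design every
    fitted model is correctly specified and there is nothing to adjust for:
    the numerator and denominator treatment models estimate the same
    quantity on both time scales (all stabilized weights are 1 up to
    sampling noise) and all estimation methods estimate the same correctly
    specified conditional survival, so their predictions agree up to Monte
    Carlo error.
    """
    base = base or DGMConfig()
    upd = dict(
        betaT_true=0.0,
        lambdaT_constant=0.2,
        lambda0_constant=0.3,
        f_linear=True,
        eta_sd=0.0,
        ou_sigma=0.0,
    )
    upd.update(overrides)
    return base.model_copy(update=upd)


def linear_variant_config(base: DGMConfig | None = None, **overrides) -> DGMConfig:
    """Variant with the post-treatment covariate effect linearized.

    f(x) = -2x everywhere (no plateaus); everything else unchanged.  Under
    this variant the treated-arm outcome model is correctly specified with
    coefficients (-2, 1) for (Zk, Z*).
    """
    base = base or DGMConfig()
    upd = dict(f_linear=True)
    upd.update(overrides)
    return base.model_copy(update=upd)


def proportional_variant_config(base: DGMConfig | None = None, **overrides) -> DGMConfig:
    """Variant of the mechanism under which every fitted model holds exactly.

    The post-treatment covariate effect is linear (f(x) = -2x), the
    covariate is constant in time per patient (no drift, no OU
    fluctuation) and the untreated-death baseline hazard is a constant
    rate, so the never-treated reset-clock hazard is exactly
    lambda * exp(beta0 * Zk) for every cross-section.  Confounding is kept
    (treatment still depends on Z), so the weights have real work to do and
    coefficient recovery is a sharp check of the whole pipeline.
    """
    base = base or DGMConfig()
    upd = dict(f_linear=True, eta_sd=0.0, ou_sigma=0.0, lambda0_constant=0.3)
    upd.update(overrides)
    return base.model_copy(update=upd)


class CovariateRoles(BaseModel):
    """Which columns play which role in estimation.

    ``patient``: time-varying patient covariates (snapshot at each
    cross-section); ``offer``: treatment-specific covariates attached to a
    cross-section's offer; ``eligibility``: optional 0/1 column gating
    cross-section inclusion; ``include_waiting_time``: add the time since
    first eligibility Sk as an outcome-model covariate.
    """

    model_config = ConfigDict(extra="forbid")

    patient: list[str] = ["Z"]
    offer: list[str] = ["Zstar"]
    eligibility: Optional[str] = None
    include_waiting_time: bool = False


class WeightOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: quantile of the pooled weight distribution used for truncation;
    #: ``None`` leaves weights uncapped (the simulation-study default)
    cap_quantile: Optional[float] = None
    #: treated-probability model intercept: one pooled intercept (default)
    intercept_mode: Literal["pooled"] = "pooled"
    #: include patient-by-offer interactions in the treated-probability model
    treated_model_interactions: bool = True
    #: rows entering the treated-probability fit: all offer dates, or only
    #: dates at which a treatment was actually delivered
    offer_dates: Literal["all", "treated_only"] = "all"
    #: risk set of the treated-probability model: every alive, untreated,
    #: uncensored patient ("at_risk", matching a receipt process that is not
    #: gated by the fitness proxy), or only patients passing the eligibility
    #: rule ("eligible", for data whose eligibility flag is authoritative)
    offer_risk_set: Literal["at_risk", "eligible"] = "at_risk"
    #: pooled or per-cross-section empirical treatment probability numerator
    lambda1_num_mode: Literal["pooled", "per_k"] = "pooled"
    #: spacing (years) of the grid on which time-varying weights are updated
    weight_update_step: float = 0.04

    @model_validator(mode="after")
    def _check(self):
        if self.cap_quantile is not None and not (0.5 < self.cap_quantile <= 1.0):
            raise ValueError("cap_quantile must lie in (0.5, 1]")
        if self.weight_update_step <= 0:
            raise ValueError("weight_update_step must be > 0")
        return self


class MSMOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    #: separate fits per arm (default) or one joint fit with arm strata
    mode: Literal["separate", "joint"] = "separate"
    #: baseline pooling across cross-sections: one pooled baseline (default),
    #: one per cross-section, or one per calendar period
    baseline: Literal["pooled", "per_k"] = "pooled"
    #: policy for predictions at future dates (pooled baseline reuses the
    #: single fitted baseline; latest/per-period are meaningful with per_k)
    prediction_policy: Literal["pooled", "latest"] = "pooled"


class EvaluationOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_runs: int = 200
    lowess_frac: float = 0.75
    #: points are trimmed to this central quantile range of the estimated
    #: values before the RMS summary (guards against smoother edge artifacts)
    trim_quantiles: tuple[float, float] = (0.01, 0.99)
    #: at most this many points enter the lowess fit (fit is interpolated
    #: onto the full point cloud afterwards)
    max_smooth_points: int = 20000
    max_failure_fraction: float = 0.10


class RunConfig(BaseModel):
    """Resolved configuration of one pipeline run."""

    model_config = ConfigDict(extra="forbid")

    dgm: DGMConfig = DGMConfig()
    roles: CovariateRoles = CovariateRoles()
    weights: WeightOptions = WeightOptions()
    msm: MSMOptions = MSMOptions()
    evaluation: EvaluationOptions = EvaluationOptions()
    output_dir: Optional[str] = None
    seed: int = 0
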