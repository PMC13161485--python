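"""Weighted marginal structural Cox models and benefit prediction.

On the weighted cross-section stacks, two proportional-hazards models are
fitted on the reset clock u: one for mortality under "never treat" and one
for post-treatment mortality given patient covariates at the cross-section
and the offer's treatment covariates.  Survival curves are composed from
the weighted Breslow baselines, restricted mean survival times (RMST) are
exact integrals of the resulting step functions, and the conditional
survival benefit of an offer is the difference of the two RMSTs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .config import CovariateRoles, MSMOptions
from .coxmodel import CoxFit, StratumBaseline, fit_cox
from .weights import WeightedStack

__all__ = [
    "MSMFit",
    "BenefitEstimate",
    "StepSurvival",
    "fit_msm",
    "predict_survival",
    "rmst_from_survival",
    "predict_benefit",
]


@dataclass
class StepSurvival:
    """Right-continuous step survival function S(u), S(0) = 1."""

    times: np.ndarray  # jump times, increasing
    values: np.ndarray  # S(u) for u in [times[i], times[i+1])

    def __call__(self, u) -> np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(u, float), side="right")
        vals = np.concatenate([[1.0], self.values])
        return vals[idx]


def rmst_from_survival(step_fn: StepSurvival, L: float) -> float:
    """Exact integral of a step survival function over [0, L]."""
    t = np.clip(step_fn.times, 0.0, L)
    edges = np.concatenate([[0.0], t, [L]])
    widths = np.diff(edges)
    vals = np.concatenate([[1.0], step_fn.values])
    return float(np.sum(vals * widths))


def _rmst_batch(baseline: StratumBaseline, lp: np.ndarray, L: float) -> np.ndarray:
    """RMST for many linear predictors sharing one baseline (exact)."""
    m = baseline.times <= L
    t = baseline.times[m]
    lam = np.cumsum(baseline.increments[m])
    edges = np.concatenate([[0.0], t, [L]])
    widths = np.diff(edges)
    lam0 = np.concatenate([[0.0], lam])
    out = np.empty(lp.size)
    chunk = max(1, int(5e6 // max(lam0.size, 1)))
    elp = np.exp(lp)
    for i in range(0, lp.size, chunk):
        sl = elp[i : i + chunk, None]
        out[i : i + chunk] = np.exp(-lam0[None, :] * sl) @ widths
    return out


@dataclass
class BenefitEstimate:
    """Estimated RMSTs and benefit for one (patient, cross-section, offer)."""

    patient_id: int
    k: int
    Sk: float
    rmst0_hat: float
    rmst1_hat: float
    benefit_hat: float
    offer_id: object = None


@dataclass
class MSMFit:
    """Fitted marginal structural model for both treatment strategies."""

    fit0: CoxFit
    fit1: CoxFit
    covariates0: list[str]
    covariates1: list[str]
    horizon: float
    options: MSMOptions
    roles: CovariateRoles
    method: str = "cs_weighted"
    diagnostics: dict = field(default_factory=dict)

    # -- linear predictors ---------------------------------------------------
    def _lp(self, fit: CoxFit, cols: list[str], df: pd.DataFrame) -> np.ndarray:
        X = df[cols].to_numpy(float) if cols else np.zeros((len(df), 0))
        return X @ fit.beta

    def _baseline(self, fit: CoxFit, df: pd.DataFrame) -> list:
        if self.options.baseline == "pooled":
            return [fit.baseline[None]] * len(df)
        return [fit.baseline[k] for k in df["k"]]

    # -- predictions ----------------------------------------------------------
    def predict_rmst0(self, df: pd.DataFrame) -> np.ndarray:
        lp = self._lp(self.fit0, self.covariates0, df)
        if self.options.baseline == "pooled":
            return _rmst_batch(self.fit0.baseline[None], lp, self.horizon)
        return np.array(
            [
                rmst_from_survival(
                    predict_survival_from(bl, l), self.horizon
                )
                for bl, l in zip(self._baseline(self.fit0, df), lp)
            ]
        )

    def predict_rmst1(self, df: pd.DataFrame) -> np.ndarray:
        lp = self._lp(self.fit1, self.covariates1, df)
        return _rmst_batch(self.fit1.baseline[None], lp, self.horizon)

    def predict_benefit_frame(self, df: pd.DataFrame) -> pd.DataFrame:
        r0 = self.predict_rmst0(df)
        r1 = self.predict_rmst1(df)
        out = df[["patient_id", "k", "Sk"]].copy()
        out["rmst0_hat"] = r0
        out["rmst1_hat"] = r1
        out["benefit_hat"] = r1 - r0
        out = out.sort_values("benefit_hat", ascending=False).reset_index(drop=True)
        out["rank"] = np.arange(1, len(out) + 1)
        return out


def predict_survival_from(baseline: StratumBaseline, lp: float) -> StepSurvival:
    return StepSurvival(baseline.times, np.exp(-np.cumsum(baseline.increments) * np.exp(lp)))


def predict_survival(fit: MSMFit, arm: Literal["never_treated", "treated_at_k"], covariates: pd.DataFrame, stratum=None) -> list[StepSurvival]:
    """Step survival functions S(u) = exp(-Lambda0(u) e^{x'beta}) per row."""
    if arm == "never_treated":
        cox, cols = fit.fit0, fit.covariates0
    else:
        cox, cols = fit.fit1, fit.covariates1
    lp = covariates[cols].to_numpy(float) @ cox.beta if cols else np.zeros(len(covariates))
    key = None if fit.options.baseline == "pooled" else stratum
    bl = cox.baseline[key]
    return [predict_survival_from(bl, l) for l in lp]


def fit_msm(
    weighted: WeightedStack,
    roles: CovariateRoles | None = None,
    options: MSMOptions | None = None,
    horizon: float | None = None,
    method_tag: str = "cs_weighted",
) -> MSMFit:
    """Fit the weighted MSM on both arms.

    ``separate`` mode fits two weighted partial-likelihood models with their
    own baselines; ``joint`` mode fits a single model stratified by arm with
    arm-specific covariate effects (equivalent predictions when fully
    interacted).  Baselines are pooled across cross-sections by default.
    """
    roles = roles or CovariateRoles()
    options = options or MSMOptions()
    cols0 = list(roles.patient) + (["Sk"] if roles.include_waiting_time else [])
    cols1 = cols0 + list(roles.offer)

    nr, tr = weighted.never_rows, weighted.treated_rows
    if not len(nr) or not nr["event"].sum():
        raise RuntimeError("cannot fit MSM: never-treated arm has no events")
    if not len(tr) or not tr["event"].sum():
        raise RuntimeError("cannot fit MSM: treated arm has no events")
    strata0 = nr["k"].to_numpy() if options.baseline == "per_k" else None

    if options.mode == "separate":
        fit0 = fit_cox(
            nr["u_start"].to_numpy(),
            nr["u_stop"].to_numpy(),
            nr["event"].to_numpy(),
            nr[cols0].to_numpy(float),
            weights=nr["weight"].to_numpy(),
            strata=strata0,
            cluster=nr["patient_id"].to_numpy(),
            names=cols0,
        )
        fit1 = fit_cox(
            tr["u_start"].to_numpy(),
            tr["u_stop"].to_numpy(),
            tr["event"].to_numpy(),
            tr[cols1].to_numpy(float),
            weights=tr["weight"].to_numpy(),
            cluster=tr["patient_id"].to_numpy(),
            names=cols1,
        )
    else:  # joint: one model, arm strata, arm-interacted covariates
        arm = np.concatenate([np.zeros(len(nr)), np.ones(len(tr))])
        both = pd.concat(
            [nr.assign(Zstar=0.0) if "Zstar" not in nr else nr, tr],
            ignore_index=True,
        )
        X0 = both[cols0].to_numpy(float) * (1 - arm)[:, None]
        X1 = both[cols1].to_numpy(float) * arm[:, None]
        Xj = np.hstack([X0, X1])
        fitj = fit_cox(
            both["u_start"].to_numpy(),
            both["u_stop"].to_numpy(),
            both["event"].to_numpy(),
            Xj,
            weights=both["weight"].to_numpy(),
            strata=arm,
            cluster=both["patient_id"].to_numpy(),
            names=[f"nt:{c}" for c in cols0] + [f"tr:{c}" for c in cols1],
        )
        fit0 = CoxFit(
            beta=fitj.beta[: len(cols0)],
            cov=fitj.cov[: len(cols0), : len(cols0)],
            names=cols0,
            baseline={None: fitj.baseline[0.0]},
            loglik=fitj.loglik,
            n_events=int(nr["event"].sum()),
            n_rows=len(nr),
            converged=fitj.converged,
        )
        fit1 = CoxFit(
            beta=fitj.beta[len(cols0) :],
            cov=fitj.cov[len(cols0) :, len(cols0) :],
            names=cols1,
            baseline={None: fitj.baseline[1.0]},
            loglik=fitj.loglik,
            n_events=int(tr["event"].sum()),
            n_rows=len(tr),
            converged=fitj.converged,
        )
    return MSMFit(
        fit0=fit0,
        fit1=fit1,
        covariates0=cols0,
        covariates1=cols1,
        horizon=horizon if horizon is not None else weightedstack_horizon(weighted),
        options=options,
        roles=roles,
        method=method_tag,
        diagnostics=dict(weighted.diagnostics),
    )


def weightedstack_horizon(weighted: WeightedStack) -> float:
    """Horizon implied by the stack (max u_stop, rounded up to 1e-6)."""
    h = 0.0
    for df in (weighted.never_rows, weighted.treated_rows):
        if len(df):
            h = max(h, float(df["u_stop"].max()))
    return h


def predict_benefit(
    fit: MSMFit, snapshots: pd.DataFrame, offer: dict | pd.Series
) -> pd.DataFrame:
    """Benefit of one offer for every eligible patient at a date, ranked.

    ``snapshots`` carries one row per eligible patient (patient_id, k, Sk,
    patient covariates); ``offer`` maps each offer covariate to its value.
    """
    if not len(snapshots):
        return pd.DataFrame(
            columns=["patient_id", "k", "Sk", "rmst0_hat", "rmst1_hat", "benefit_hat", "rank"]
        )
    df = snapshots.copy()
    for c in fit.roles.offer:
        df[c] = offer[c]
    return fit.predict_benefit_frame(df)
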