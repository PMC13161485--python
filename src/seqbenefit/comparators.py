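"""Baseline estimation methods the weighted cross-section MSM is compared to.

* ``naive``: unadjusted Cox models from a single time origin -- entry for
  never-treated mortality (baseline covariate Z(0)), treatment time for
  post-treatment mortality (covariates Z(T) and the offer's Z*).  Residual
  predictions at a cross-section condition the fitted survival curve on
  survival to Sk.
* ``cs_unweighted``: the identical cross-section stacking pipeline as the
  proposed method but with all weights equal to one.

Both expose the same prediction interface as :class:`seqbenefit.msm.MSMFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CovariateRoles, MSMOptions
from .cohort import CrossSectionStack
from .coxmodel import CoxFit, fit_cox
from .msm import MSMFit, _rmst_batch, fit_msm
from .weights import WeightedStack

__all__ = ["NaiveFit", "fit_naive", "fit_cs_unweighted"]


@dataclass
class NaiveFit:
    """Unadjusted single-origin Cox models with the MSM prediction API."""

    fit0: CoxFit
    fit1: CoxFit
    covariates0: list[str]
    covariates1: list[str]
    z0_by_patient: pd.DataFrame  # baseline covariates per patient
    horizon: float
    roles: CovariateRoles
    method: str = "naive"
    diagnostics: dict = field(default_factory=dict)

    def predict_rmst0(self, df: pd.DataFrame) -> np.ndarray:
        """Residual RMST over [Sk, Sk+L] from the single-origin fit.

        S(Sk+u)/S(Sk) with the patient's baseline covariate Z(0); exact
        step-function integral.
        """
        z0 = self.z0_by_patient.reindex(df["patient_id"].to_numpy())
        lp = z0[self.covariates0].to_numpy(float) @ self.fit0.beta
        sk = df["Sk"].to_numpy(float)
        base = self.fit0.baseline[None]
        tau = base.times
        cum = np.concatenate([[0.0], np.cumsum(base.increments)])
        edges = np.concatenate([[0.0], tau, [np.inf]])
        L = self.horizon
        out = np.empty(len(df))
        chunk = max(1, int(5e6 // max(edges.size, 1)))
        for i in range(0, len(df), chunk):
            s = sk[i : i + chunk, None]
            e = np.exp(lp[i : i + chunk, None])
            lo = np.clip(edges[None, :-1], s, s + L)
            hi = np.clip(edges[None, 1:], s, s + L)
            w = hi - lo
            lam_sk_idx = np.searchsorted(tau, sk[i : i + chunk], side="right")
            lam_sk = cum[lam_sk_idx]
            surv = np.exp(-np.maximum(cum[None, :] - lam_sk[:, None], 0.0) * e)
            out[i : i + chunk] = np.sum(surv * w, axis=1)
        return out

    def predict_rmst1(self, df: pd.DataFrame) -> np.ndarray:
        lp = df[self.covariates1].to_numpy(float) @ self.fit1.beta
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


def fit_naive(
    episodes: pd.DataFrame,
    covariates,
    roles: CovariateRoles | None = None,
    horizon: float = 3.0,
) -> NaiveFit:
    """Fit the naive comparator.

    Never-treated mortality: Cox from entry with Z(0), censoring at
    treatment or administrative end.  Post-treatment mortality: Cox on the
    residual scale from treatment with Z(T) and the offer covariates,
    truncated at the horizon.
    """
    roles = roles or CovariateRoles()
    if not len(episodes):
        raise RuntimeError("cannot fit naive comparator: no episodes")
    pid = episodes["patient_id"].to_numpy()
    z0 = covariates.snapshot(pid, np.zeros(pid.size))
    z0.index = pid
    X = episodes["X"].to_numpy()
    delta = episodes["delta"].to_numpy().astype(bool)
    fit0 = fit_cox(
        np.zeros(pid.size), X, delta, z0[roles.patient].to_numpy(float),
        cluster=pid, names=list(roles.patient),
    )

    tr = episodes[episodes["treated"].astype(bool)].reset_index(drop=True)
    zT = covariates.snapshot(tr["patient_id"].to_numpy(), tr["T"].to_numpy())
    resid = tr["post_time"].to_numpy()
    u_stop = np.minimum(resid, horizon)
    ev1 = tr["post_delta"].to_numpy().astype(bool) & (resid <= horizon)
    cols1 = list(roles.patient) + list(roles.offer)
    X1 = np.column_stack(
        [zT[roles.patient].to_numpy(float), tr[roles.offer].to_numpy(float)]
    )
    fit1 = fit_cox(
        np.zeros(len(tr)), u_stop, ev1, X1,
        cluster=tr["patient_id"].to_numpy(), names=cols1,
    )
    return NaiveFit(
        fit0=fit0,
        fit1=fit1,
        covariates0=list(roles.patient),
        covariates1=cols1,
        z0_by_patient=z0,
        horizon=horizon,
        roles=roles,
    )


def fit_cs_unweighted(
    never_stack: CrossSectionStack,
    treated_stack: CrossSectionStack,
    roles: CovariateRoles | None = None,
    options: MSMOptions | None = None,
    horizon: float = 3.0,
) -> MSMFit:
    """The proposed pipeline with all weights set to one."""
    nr = never_stack.rows.copy()
    tr = treated_stack.rows.copy()
    nr["weight"] = 1.0
    tr["weight"] = 1.0
    ws = WeightedStack(never_rows=nr, treated_rows=tr, diagnostics={"unweighted": True})
    return fit_msm(
        ws, roles=roles, options=options, horizon=horizon, method_tag="cs_unweighted"
    )
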