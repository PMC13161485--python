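"""Stabilized inverse-probability-of-treatment weights.

Three fitted components produce the weights that turn the stacked
cross-section data into a pseudo-population in which treatment assignment
is unconfounded:

* a Cox model on the original follow-up scale for time-to-treatment with
  the time-varying covariate history (denominator for the never-treated
  arm);
* a Cox model on the reset clock, stratified by cross-section with
  covariates frozen at the cross-section date (numerator / stabilizer);
* a complementary log-log regression for receipt of the specific offer at
  a cross-section, given patient and offer covariates (denominator for the
  treated arm), stabilized by the pooled empirical treatment probability.

Never-treated-arm weights are time-varying step functions; rows are
expanded on a weight-update grid and both cumulative hazards are evaluated
at interval right endpoints via the fitted Breslow step functions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import CovariateRoles, WeightOptions
from .cohort import CrossSectionStack
from .coxmodel import CoxFit, fit_cox

__all__ = [
    "WeightModelSet",
    "WeightedStack",
    "PositivityError",
    "fit_denominator_model",
    "fit_numerator_model",
    "fit_treated_probability_model",
    "compute_weights",
    "stabilized_weight_from_cumhaz",
]


class PositivityError(RuntimeError):
    """A treated row has an estimated treatment probability of zero."""


def _outcome_covariates(roles: CovariateRoles) -> list[str]:
    cols = list(roles.patient)
    if roles.include_waiting_time:
        cols.append("Sk")
    return cols


# ---------------------------------------------------------------------------
# denominator: time-to-treatment on the original follow-up scale


def fit_denominator_model(
    episodes: pd.DataFrame,
    covariates,
    roles: CovariateRoles | None = None,
) -> CoxFit:
    """Cox model for time-to-treatment with time-varying covariates.

    Treatment is the event; untreated death and administrative censoring
    censor.  Episodes are split at the observed treatment times (the only
    times at which the partial likelihood and the Breslow baseline evaluate
    the covariate), with the covariate carried from the measurement history.
    """
    roles = roles or CovariateRoles()
    X = episodes["X"].to_numpy()
    treated = episodes["treated"].to_numpy().astype(bool)
    pid = episodes["patient_id"].to_numpy()
    if not treated.any():
        raise RuntimeError("cannot fit denominator model: no treatment events")
    ev = np.sort(X[treated])

    cnt = np.searchsorted(ev, X, side="left")  # internal breakpoints per patient
    total = cnt + 1
    row_pat = np.repeat(np.arange(X.size), total)
    offs = np.concatenate([[0], np.cumsum(total)])[:-1]
    within = np.arange(total.sum()) - np.repeat(offs, total)
    last = within == cnt[row_pat]
    starts = np.where(within == 0, 0.0, ev[np.maximum(within - 1, 0)])
    stops = np.where(last, X[row_pat], ev[np.minimum(within, ev.size - 1)])
    event = last & treated[row_pat]
    keep = stops > starts
    row_pat, starts, stops, event = row_pat[keep], starts[keep], stops[keep], event[keep]
    snap = covariates.snapshot(pid[row_pat], stops)
    Xmat = snap[roles.patient].to_numpy()
    return fit_cox(
        starts, stops, event, Xmat, cluster=pid[row_pat], names=list(roles.patient)
    )


# ---------------------------------------------------------------------------
# numerator: time-to-treatment from each cross-section, frozen covariates


def fit_numerator_model(
    never_stack: CrossSectionStack,
    roles: CovariateRoles | None = None,
) -> CoxFit:
    """Stabilizer model on the reset clock, stratified by cross-section.

    Treatment (artificial censoring of the never-treated arm) is the event;
    covariates are frozen at the cross-section date; each cross-section has
    its own baseline hazard while coefficients are shared.
    """
    roles = roles or CovariateRoles()
    rows = never_stack.rows
    if not len(rows):
        raise RuntimeError("cannot fit numerator model: empty stack")
    cols = _outcome_covariates(roles)
    fit = fit_cox(
        rows["u_start"].to_numpy(),
        rows["u_stop"].to_numpy(),
        rows["artificial_censor"].to_numpy(),
        rows[cols].to_numpy() if cols else np.zeros((len(rows), 0)),
        strata=rows["k"].to_numpy(),
        names=cols,
    )
    for fl in fit.flags:
        if "no events" in fl:
            logging.getLogger("seqbenefit").info("numerator model: %s", fl)
    return fit


# ---------------------------------------------------------------------------
# treated-probability model (complementary log-log)


@dataclass
class ClogLogModel:
    """Fitted cloglog regression P(treated) = 1 - exp(-exp(eta))."""

    params: np.ndarray
    columns: list[str]
    interactions: list[tuple[str, str]]
    se: np.ndarray | None = None
    ridged: bool = False

    def design(self, df: pd.DataFrame) -> np.ndarray:
        cols = [np.ones(len(df))]
        cols += [df[c].to_numpy(float) for c in self.columns]
        cols += [df[a].to_numpy(float) * df[b].to_numpy(float) for a, b in self.interactions]
        return np.column_stack(cols)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        return self.design(df) @ self.params

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return 1.0 - np.exp(-np.exp(self.linear_predictor(df)))


def fit_treated_probability_model(
    offer_snapshots: pd.DataFrame,
    roles: CovariateRoles | None = None,
    options: WeightOptions | None = None,
) -> ClogLogModel:
    """cloglog regression of offer receipt on patient and offer covariates.

    One pooled intercept across cross-sections (scarce treatment: few
    recipients per date).  Complete separation triggers a ridge-stabilized
    refit with a warning.
    """
    roles = roles or CovariateRoles()
    options = options or WeightOptions()
    cols = list(roles.patient) + list(roles.offer)
    inter = (
        [(a, b) for a in roles.patient for b in roles.offer]
        if options.treated_model_interactions
        else []
    )
    model = ClogLogModel(np.zeros(1 + len(cols) + len(inter)), cols, inter)
    Xd = model.design(offer_snapshots)
    y = offer_snapshots["treated_flag"].to_numpy(float)
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    glm = sm.GLM(y, Xd, family=fam)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(maxiter=200)
        params = np.asarray(res.params)
        if not np.all(np.isfinite(params)) or np.abs(params).max() > 50:
            raise RuntimeError("divergent cloglog fit")
        se = np.asarray(res.bse)
        ridged = False
    except Exception:
        warnings.warn("cloglog separation/divergence; ridge-stabilized refit")
        res = glm.fit_regularized(alpha=1e-4, L1_wt=0.0)
        params = np.asarray(res.params)
        se = None
        ridged = True
    model.params = params
    model.se = se
    model.ridged = ridged
    return model


# ---------------------------------------------------------------------------
# weight assembly


@dataclass
class WeightModelSet:
    """The three fitted treatment-model components plus stabilization."""

    denominator: CoxFit
    numerator: CoxFit
    treated_prob: ClogLogModel
    lambda1_num: float | pd.Series
    roles: CovariateRoles
    options: WeightOptions

    def lambda1_num_at(self, date_idx: np.ndarray) -> np.ndarray:
        if np.isscalar(self.lambda1_num) or isinstance(self.lambda1_num, float):
            return np.full(np.asarray(date_idx).size, float(self.lambda1_num))
        return self.lambda1_num.reindex(np.asarray(date_idx)).fillna(0.0).to_numpy()


def estimate_lambda1_num(
    offer_snapshots: pd.DataFrame, options: WeightOptions | None = None
) -> float | pd.Series:
    """Empirical per-offer treatment probability (pooled by default)."""
    options = options or WeightOptions()
    if options.lambda1_num_mode == "pooled":
        return float(offer_snapshots["treated_flag"].mean())
    return offer_snapshots.groupby("date_idx")["treated_flag"].mean()


@dataclass
class WeightedStack:
    """Interval-expanded stacks with attached stabilized weights."""

    never_rows: pd.DataFrame  # counting-process layout with 'weight'
    treated_rows: pd.DataFrame
    diagnostics: dict = field(default_factory=dict)


def stabilized_weight_from_cumhaz(num_cum, den_cum) -> np.ndarray:
    """W = exp(-Lambda_num) / exp(-Lambda_den), elementwise."""
    return np.exp(np.asarray(den_cum, float) - np.asarray(num_cum, float))


def _expand_never_rows(rows: pd.DataFrame, step: float) -> pd.DataFrame:
    """Split each row's (0, u_stop] into weight-update intervals."""
    u_stop = rows["u_stop"].to_numpy()
    n_int = np.ceil(u_stop / step - 1e-9).astype(int)
    n_int = np.maximum(n_int, 1)
    ridx = np.repeat(np.arange(len(rows)), n_int)
    offs = np.concatenate([[0], np.cumsum(n_int)])[:-1]
    within = np.arange(n_int.sum()) - np.repeat(offs, n_int)
    a = within * step
    b = np.minimum((within + 1) * step, u_stop[ridx])
    last = within == n_int[ridx] - 1
    out = rows.iloc[ridx].reset_index(drop=True)
    out["u_start"] = a
    out["u_stop"] = b
    out["event"] = np.where(last, rows["event"].to_numpy()[ridx], 0)
    out["artificial_censor"] = np.where(
        last, rows["artificial_censor"].to_numpy()[ridx], 0
    )
    return out


def compute_weights(
    never_stack: CrossSectionStack,
    treated_stack: CrossSectionStack,
    models: WeightModelSet,
    covariates,
) -> WeightedStack:
    """Attach stabilized (optionally capped) weights to both arms.

    Never-treated rows are expanded on the weight-update grid; for each
    interval the weight is exp(Lambda_den(Sk, Sk+u] - Lambda_num,k(u]) with
    both cumulative hazards evaluated at the interval's right endpoint u.
    Treated rows get the time-constant weight lambda1_num / P(offer receipt).
    """
    roles, options = models.roles, models.options
    cols = _outcome_covariates(roles)

    never = _expand_never_rows(never_stack.rows, options.weight_update_step)
    b = never["u_stop"].to_numpy()
    sk = never["Sk"].to_numpy()
    karr = never["k"].to_numpy()
    # numerator: stratified Breslow baseline x exp(beta_num' Zk)
    num_cols = cols
    lp_num = (
        never[num_cols].to_numpy() @ models.numerator.beta
        if num_cols
        else np.zeros(len(never))
    )
    lam_num = np.empty(len(never))
    for k in np.unique(karr):
        m = karr == k
        lam_num[m] = models.numerator.baseline[k].cumhaz(b[m])
    lam_num *= np.exp(lp_num)

    # denominator: per-patient integral of the fitted treatment hazard along
    # the covariate path over (Sk, Sk+u]
    den = models.denominator
    base = den.baseline[None]
    tj, dL = base.times, base.increments
    pids = never["patient_id"].to_numpy()
    upid, pinv = np.unique(pids, return_inverse=True)
    # covariate of each (unique patient, event time) pair
    snap = covariates.snapshot(
        np.repeat(upid, tj.size), np.tile(tj, upid.size)
    )
    zmat = snap[roles.patient].to_numpy() @ den.beta
    C = np.cumsum(
        np.exp(zmat).reshape(upid.size, tj.size) * dL[None, :], axis=1
    )
    C = np.concatenate([np.zeros((upid.size, 1)), C], axis=1)
    hi = np.searchsorted(tj, sk + b, side="right")
    lo = np.searchsorted(tj, sk, side="right")
    lam_den = C[pinv, hi] - C[pinv, lo]
    never["weight"] = stabilized_weight_from_cumhaz(lam_num, lam_den)

    treated = treated_stack.rows.copy()
    if len(treated):
        phat = models.treated_prob.predict(treated)
        bad = phat <= 0
        if bad.any():
            j = treated.index[bad][0]
            raise PositivityError(
                f"estimated treatment probability is 0 for treated row {j} "
                f"(patient {treated.loc[j, 'patient_id']})"
            )
        treated["weight"] = models.lambda1_num_at(treated["k"].to_numpy()) / phat
    else:
        treated["weight"] = pd.Series(dtype=float)

    pooled = np.concatenate([never["weight"].to_numpy(), treated["weight"].to_numpy()])
    diag = {
        "mean_before": float(pooled.mean()),
        "max_before": float(pooled.max()),
        "cap_quantile": options.cap_quantile,
    }
    if options.cap_quantile is not None and options.cap_quantile < 1.0:
        cap = float(np.quantile(pooled, options.cap_quantile))
        never["weight"] = np.minimum(never["weight"], cap)
        treated["weight"] = np.minimum(treated["weight"], cap)
        diag["cap_value"] = cap
    allw = np.concatenate([never["weight"].to_numpy(), treated["weight"].to_numpy()])
    diag["mean_after"] = float(allw.mean())
    diag["max_after"] = float(allw.max())
    diag["ess"] = float(allw.sum() ** 2 / (allw**2).sum())
    return WeightedStack(never_rows=never, treated_rows=treated, diagnostics=diag)


def weight_diagnostics_frame(stack: WeightedStack) -> pd.DataFrame:
    """Per-cross-section weight summaries (for reporting)."""
    recs = []
    for arm, df in (("never_treated", stack.never_rows), ("treated_at_k", stack.treated_rows)):
        if not len(df):
            continue
        g = df.groupby("k")["weight"]
        rec = g.agg(["mean", "max", "count"]).reset_index()
        rec["arm"] = arm
        recs.append(rec)
    return pd.concat(recs, ignore_index=True) if recs else pd.DataFrame()
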