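"""Cross-section cohort construction on the reset clock u = t - Sk.

At every calendar date a treatment becomes available, the patients who are
alive, untreated, uncensored and fit for treatment just before that date
form a new trial-like cohort whose clock starts at the date.  Two stacked
datasets are built:

* the never-treated arm, over a coarse date grid: each eligible patient
  contributes follow-up from the date until death, deviation (treatment --
  artificial censoring) or the horizon;
* the treated arm, over a fine date grid: each treated patient contributes
  post-treatment follow-up at the single cross-section matching their
  treatment date, carrying the delivered offer's covariates.

Stacks are emitted with one row per (patient, cross-section, arm); interval
expansion for time-varying weights happens in :mod:`seqbenefit.weights`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CovariateRoles
from .simulate import OfferStream, Population

__all__ = [
    "CrossSectionStack",
    "PopulationCovariates",
    "LongTableCovariates",
    "snapshot_covariates",
    "build_never_treated_stack",
    "build_treated_stack",
    "build_offer_snapshots",
]

NEVER_TREATED = "never_treated"
TREATED_AT_K = "treated_at_k"


@dataclass
class CrossSectionStack:
    """Stacked per-(patient, cross-section) records for one arm."""

    rows: pd.DataFrame
    arm: str
    horizon: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        r = self.rows
        if len(r):
            if (r["u_stop"] > self.horizon + 1e-9).any():
                raise ValueError("u_stop exceeds the horizon")
            if (r["u_stop"] <= r["u_start"]).any():
                raise ValueError("degenerate interval (u_start >= u_stop)")

    def __len__(self):
        return len(self.rows)


class PopulationCovariates:
    """Covariate source backed by a simulated population's grid paths."""

    def __init__(self, pop: Population):
        self.pop = pop
        self.columns = ["Z"]

    def snapshot(self, ids, times) -> pd.DataFrame:
        z = self.pop.z_at(np.asarray(ids, int), np.maximum(np.asarray(times, float), 0.0))
        return pd.DataFrame({"Z": z})


class LongTableCovariates:
    """Covariate source backed by a long-format measurement table.

    ``measurements`` must have an id column, a follow-up time column and one
    column per covariate; values are carried forward from the last
    measurement at or before the requested time.
    """

    def __init__(self, measurements: pd.DataFrame, columns, id_col="patient_id", time_col="t"):
        self.meas = measurements.sort_values([id_col, time_col]).reset_index(drop=True)
        self.columns = list(columns)
        self.id_col = id_col
        self.time_col = time_col

    def snapshot(self, ids, times) -> pd.DataFrame:
        return snapshot_covariates(
            self.meas, ids, times, self.columns, self.id_col, self.time_col
        )


def snapshot_covariates(
    measurements: pd.DataFrame, ids, times, columns, id_col="patient_id", time_col="t"
) -> pd.DataFrame:
    """Last-observation-carried-forward covariates at (id, time) pairs.

    Rows with no measurement at or before the requested time get NaN; the
    caller is expected to drop them (missing-covariate exclusion).
    """
    q = pd.DataFrame({id_col: np.asarray(ids), time_col: np.asarray(times, float)})
    q["_order"] = np.arange(len(q))
    q = q.sort_values([time_col, id_col], kind="stable")
    m = measurements.sort_values([time_col, id_col], kind="stable")
    out = pd.merge_asof(
        q,
        m[[id_col, time_col] + list(columns)],
        on=time_col,
        by=id_col,
        direction="backward",
        allow_exact_matches=True,
    )
    out = out.sort_values("_order")
    return out[list(columns)].reset_index(drop=True)


def _default_eligibility(snapshot: pd.DataFrame, threshold: float) -> np.ndarray:
    return snapshot["Z"].to_numpy() > threshold


def build_never_treated_stack(
    episodes: pd.DataFrame,
    covariates,
    dates_coarse: np.ndarray,
    horizon: float,
    roles: CovariateRoles | None = None,
    eligibility_threshold: float = -1.0,
) -> CrossSectionStack:
    """Stack of never-treated-arm records over the coarse date grid.

    For each date, every patient alive, untreated, uncensored just before
    the date and eligible at it contributes follow-up from u = 0 to
    min(death, treatment, censoring, horizon) with covariates frozen at the
    date; treatment within the horizon becomes artificial censoring.
    """
    roles = roles or CovariateRoles()
    dates = np.asarray(dates_coarse, float)
    s_entry = episodes["s_entry"].to_numpy()
    X = episodes["X"].to_numpy()
    delta = episodes["delta"].to_numpy().astype(bool)
    treated = episodes["treated"].to_numpy().astype(bool)
    pid = episodes["patient_id"].to_numpy()

    # dense (patient x date) at-risk mask, then extract candidate pairs
    Sk = dates[None, :] - s_entry[:, None]
    at_risk = (Sk >= 0.0) & (X[:, None] > Sk)
    ii, kk = np.nonzero(at_risk)
    if ii.size == 0:
        warnings.warn("empty risk set at every cross-section date")
        return CrossSectionStack(_empty_rows(roles), NEVER_TREATED, horizon)
    sk = Sk[ii, kk]
    snap = covariates.snapshot(pid[ii], sk)
    n_candidates = ii.size
    if roles.eligibility is not None:
        elig = snap[roles.eligibility].to_numpy() > 0
    else:
        elig = _default_eligibility(snap, eligibility_threshold)
    missing = snap[roles.patient].isna().any(axis=1).to_numpy()
    keep = elig & ~missing
    ii, kk, sk = ii[keep], kk[keep], sk[keep]
    snap = snap.loc[keep].reset_index(drop=True)

    resid = X[ii] - sk
    u_stop = np.minimum(resid, horizon)
    event = delta[ii] & (resid <= horizon)
    art = treated[ii] & (resid <= horizon)
    rows = pd.DataFrame(
        {
            "patient_id": pid[ii],
            "k": kk,
            "cs_date": dates[kk],
            "Sk": sk,
            "arm": NEVER_TREATED,
            "u_start": 0.0,
            "u_stop": u_stop,
            "event": event.astype(int),
            "artificial_censor": art.astype(int),
        }
    )
    for c in roles.patient:
        rows[c] = snap[c].to_numpy()
    prov = {
        "dates": dates,
        "n_candidates": int(n_candidates),
        "n_excluded_ineligible": int((~elig).sum()),
        "n_excluded_missing": int((missing & elig).sum()) if roles.patient else 0,
    }
    return CrossSectionStack(rows, NEVER_TREATED, horizon, prov)


def build_treated_stack(
    episodes: pd.DataFrame,
    covariates,
    offer_stream: OfferStream,
    horizon: float,
    roles: CovariateRoles | None = None,
    eligibility_threshold: float = -1.0,
    spacing_fine: float | None = None,
) -> CrossSectionStack:
    """Stack of treated-arm records, one cross-section per delivered offer.

    Each treated patient is assigned to the fine date their treatment
    calendar time rounds to (nearest, ties toward the earlier date) and
    contributes post-treatment follow-up from u = 0 to min(post-treatment
    death, censoring, horizon) with the delivered offer's covariates.
    Treatments at calendar dates beyond the cross-section window carry no
    cross-section and are skipped (counted in provenance).
    """
    roles = roles or CovariateRoles()
    dates = offer_stream.dates_fine
    if spacing_fine is None:
        if dates.size < 2:
            raise ValueError("cannot infer fine spacing from a single date")
        spacing_fine = float(dates[1] - dates[0])
    ep = episodes[episodes["treated"].astype(bool)].reset_index(drop=True)
    t_cal = ep["s_entry"].to_numpy() + ep["T"].to_numpy()
    didx = np.ceil(t_cal / spacing_fine - 0.5).astype(int)
    in_grid = (didx >= 0) & (didx < dates.size)
    n_out = int((~in_grid).sum())
    beyond = t_cal >= dates[-1] + spacing_fine / 2
    if np.any(~in_grid & ~beyond):
        raise ValueError("a treatment date inside the window failed to map to the grid")
    ep = ep.loc[in_grid].reset_index(drop=True)
    didx = didx[in_grid]

    sk = np.maximum(dates[didx] - ep["s_entry"].to_numpy(), 0.0)
    snap = covariates.snapshot(ep["patient_id"].to_numpy(), sk)
    # receipt of treatment at the date implies availability for treatment,
    # so recipients are eligible at their own cross-section by definition;
    # only rows with missing covariates are dropped
    missing = snap[roles.patient].isna().any(axis=1).to_numpy()
    keep = ~missing
    ep = ep.loc[keep].reset_index(drop=True)
    didx, sk = didx[keep], sk[keep]
    snap = snap.loc[keep].reset_index(drop=True)
    if roles.eligibility is not None:
        n_flagged = int((snap[roles.eligibility].to_numpy() <= 0).sum())
    else:
        n_flagged = int((~_default_eligibility(snap, eligibility_threshold)).sum())

    resid = ep["post_time"].to_numpy()
    u_stop = np.minimum(resid, horizon)
    event = ep["post_delta"].to_numpy().astype(bool) & (resid <= horizon)
    # multiple treatments at one date: separate cross-section copies
    seq = pd.Series(np.zeros(len(ep), dtype=int)).groupby(didx).cumcount().to_numpy()
    rows = pd.DataFrame(
        {
            "patient_id": ep["patient_id"].to_numpy(),
            "k": didx,
            "offer_seq": seq,
            "cs_date": dates[didx],
            "Sk": sk,
            "arm": TREATED_AT_K,
            "u_start": 0.0,
            "u_stop": u_stop,
            "event": event.astype(int),
            "artificial_censor": 0,
        }
    )
    for c in roles.patient:
        rows[c] = snap[c].to_numpy()
    rows["Zstar"] = ep["Zstar"].to_numpy()
    prov = {
        "n_treated": int(episodes["treated"].sum()),
        "n_outside_date_window": n_out,
        "n_recipients_below_threshold": n_flagged,
        "n_excluded_missing": int(missing.sum()),
    }
    return CrossSectionStack(rows, TREATED_AT_K, horizon, prov)


def build_offer_snapshots(
    episodes: pd.DataFrame,
    covariates,
    offer_stream: OfferStream,
    roles: CovariateRoles | None = None,
    eligibility_threshold: float = -1.0,
    dates: str = "all",
) -> pd.DataFrame:
    """(eligible patient, offer) rows for the treated-probability model.

    One row per eligible patient per offer, carrying the patient snapshot at
    the offer date, the offer's treatment covariates, and a flag marking the
    actual recipient.  ``dates='treated_only'`` restricts to offers that
    were delivered.
    """
    roles = roles or CovariateRoles()
    offers = offer_stream.offers
    if dates == "treated_only":
        offers = offers[offers["patient_id"] >= 0]
    offers = offers.reset_index(drop=True)
    s_entry = episodes["s_entry"].to_numpy()
    X = episodes["X"].to_numpy()
    pid = episodes["patient_id"].to_numpy()

    d = offers["date"].to_numpy()
    Sk = d[None, :] - s_entry[:, None]
    at_risk = (Sk >= 0.0) & (X[:, None] > Sk)
    # a recipient's follow-up ends exactly at their own offer date (X = T),
    # which date rounding can push to X <= Sk; force them back into their
    # own cross-section's risk set
    rec = offers["patient_id"].to_numpy()
    pos_of_pid = pd.Series(np.arange(pid.size), index=pid)
    has_rec = rec >= 0
    rec_pos = pos_of_pid.reindex(rec[has_rec]).to_numpy()
    valid = ~pd.isna(rec_pos)
    at_risk[rec_pos[valid].astype(int), np.flatnonzero(has_rec)[valid]] = True
    ii, jj = np.nonzero(at_risk)
    sk = np.maximum(Sk[ii, jj], 0.0)
    snap = covariates.snapshot(pid[ii], sk)
    if roles.eligibility is not None:
        elig = snap[roles.eligibility].to_numpy() > 0
    else:
        elig = _default_eligibility(snap, eligibility_threshold)
    missing = snap[roles.patient].isna().any(axis=1).to_numpy()
    # the actual recipient of an offer is eligible at that offer's date by
    # definition (they received it), whatever the covariate threshold says
    is_recipient = pid[ii] == rec[jj]
    keep = (elig | is_recipient) & ~missing
    ii, jj, sk = ii[keep], jj[keep], sk[keep]
    snap = snap.loc[keep].reset_index(drop=True)
    out = pd.DataFrame(
        {
            "patient_id": pid[ii],
            "offer_row": jj,
            "date_idx": offers["date_idx"].to_numpy()[jj],
            "cs_date": d[jj],
            "Sk": sk,
            "treated_flag": (pid[ii] == rec[jj]).astype(int),
        }
    )
    for c in roles.patient:
        out[c] = snap[c].to_numpy()
    out["Zstar"] = offers["Zstar"].to_numpy()[jj]
    return out


def _empty_rows(roles: CovariateRoles) -> pd.DataFrame:
    cols = [
        "patient_id",
        "k",
        "cs_date",
        "Sk",
        "arm",
        "u_start",
        "u_stop",
        "event",
        "artificial_censor",
    ] + list(roles.patient)
    return pd.DataFrame({c: [] for c in cols})
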