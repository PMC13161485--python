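"""End-to-end orchestration: population -> stacks -> weights -> fits -> points.

Thin glue used by the evaluation harness, the CLI and the examples; every
step is an ordinary library call so the pieces remain usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cohort
from .config import RunConfig
from .msm import MSMFit, fit_msm
from .simulate import Population, true_rmst0_batch, true_rmst1
from .comparators import NaiveFit, fit_cs_unweighted, fit_naive
from .weights import (
    WeightModelSet,
    compute_weights,
    estimate_lambda1_num,
    fit_denominator_model,
    fit_numerator_model,
    fit_treated_probability_model,
)

__all__ = ["Stacks", "build_stacks", "fit_weight_models", "fit_method", "evaluation_points"]

METHODS = ("cs_weighted", "cs_unweighted", "naive")


@dataclass
class Stacks:
    never: cohort.CrossSectionStack
    treated: cohort.CrossSectionStack
    offer_snapshots: pd.DataFrame
    covariates: object


def build_stacks(pop: Population, cfg: RunConfig) -> Stacks:
    cov = cohort.PopulationCovariates(pop)
    dgm = pop.config
    never = cohort.build_never_treated_stack(
        pop.episodes,
        cov,
        pop.offer_stream.dates_coarse,
        dgm.horizon_L,
        cfg.roles,
        dgm.eligibility_threshold,
    )
    treated = cohort.build_treated_stack(
        pop.episodes,
        cov,
        pop.offer_stream,
        dgm.horizon_L,
        cfg.roles,
        dgm.eligibility_threshold,
        spacing_fine=dgm.cs_spacing_fine,
    )
    offer_thr = (
        -np.inf if cfg.weights.offer_risk_set == "at_risk" else dgm.eligibility_threshold
    )
    snaps = cohort.build_offer_snapshots(
        pop.episodes,
        cov,
        pop.offer_stream,
        cfg.roles,
        offer_thr,
        dates=("treated_only" if cfg.weights.offer_dates == "treated_only" else "all"),
    )
    return Stacks(never=never, treated=treated, offer_snapshots=snaps, covariates=cov)


def fit_weight_models(stacks: Stacks, episodes: pd.DataFrame, cfg: RunConfig) -> WeightModelSet:
    den = fit_denominator_model(episodes, stacks.covariates, cfg.roles)
    num = fit_numerator_model(stacks.never, cfg.roles)
    prob = fit_treated_probability_model(stacks.offer_snapshots, cfg.roles, cfg.weights)
    lam1 = estimate_lambda1_num(stacks.offer_snapshots, cfg.weights)
    return WeightModelSet(
        denominator=den,
        numerator=num,
        treated_prob=prob,
        lambda1_num=lam1,
        roles=cfg.roles,
        options=cfg.weights,
    )


def fit_method(pop: Population, cfg: RunConfig, method: str, stacks: Stacks | None = None):
    """Fit one of the three estimation methods on a population."""
    if stacks is None:
        stacks = build_stacks(pop, cfg)
    L = pop.config.horizon_L
    if method == "naive":
        return fit_naive(pop.episodes, stacks.covariates, cfg.roles, horizon=L)
    if method == "cs_unweighted":
        return fit_cs_unweighted(stacks.never, stacks.treated, cfg.roles, cfg.msm, horizon=L)
    if method == "cs_weighted":
        models = fit_weight_models(stacks, pop.episodes, cfg)
        weighted = compute_weights(stacks.never, stacks.treated, models, stacks.covariates)
        return fit_msm(weighted, cfg.roles, cfg.msm, horizon=L, method_tag="cs_weighted")
    raise ValueError(f"unknown method {method!r}")


def evaluation_points(pop: Population, stacks: Stacks) -> pd.DataFrame:
    """(patient, coarse cross-section) evaluation points with ground truth.

    One row per eligible patient per coarse date, carrying the frozen
    covariates, the date's offer quality Z*, and the true RMSTs and benefit
    computed from the latent trajectories.
    """
    rows = stacks.never.rows
    dgm = pop.config
    ratio = int(round(dgm.cs_spacing_coarse / dgm.cs_spacing_fine))
    zstar_fine = pop.offer_stream.zstar_primary()
    fine_idx = rows["k"].to_numpy() * ratio
    pts = rows[["patient_id", "k", "cs_date", "Sk"] + [c for c in ["Z"] if c in rows]].copy()
    pts["Zstar"] = zstar_fine[fine_idx]
    pts["true_rmst0"] = true_rmst0_batch(
        pop, pts["patient_id"].to_numpy(), pts["Sk"].to_numpy()
    )
    pts["true_rmst1"] = true_rmst1(
        pts["Z"].to_numpy(), pts["Zstar"].to_numpy(), dgm
    )
    pts["true_benefit"] = pts["true_rmst1"] - pts["true_rmst0"]
    return pts


def predict_points(fit, points: pd.DataFrame) -> pd.DataFrame:
    """Attach a method's three estimands to the evaluation points."""
    out = points.copy()
    out["est_rmst0"] = fit.predict_rmst0(points)
    out["est_rmst1"] = fit.predict_rmst1(points)
    out["est_benefit"] = out["est_rmst1"] - out["est_rmst0"]
    return out
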