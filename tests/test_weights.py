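"""Weight-model components and stabilized-weight assembly."""

import numpy as np
import pandas as pd
import pytest

from seqbenefit.cohort import LongTableCovariates, PopulationCovariates, build_never_treated_stack
from seqbenefit.config import CovariateRoles, DGMConfig, RunConfig, WeightOptions
from seqbenefit.pipeline import build_stacks, fit_weight_models
from seqbenefit.simulate import generate_population
from seqbenefit.weights import (
    ClogLogModel,
    PositivityError,
    compute_weights,
    fit_denominator_model,
    fit_numerator_model,
    fit_treated_probability_model,
    stabilized_weight_from_cumhaz,
)

from conftest import TOY_T, TOY_Z, toy_episodes, toy_measurements


class TestDenominatorModel:
    def test_toy_coefficient(self, toy_oracle_beta):
        fit = fit_denominator_model(
            toy_episodes(as_treatment=True),
            LongTableCovariates(toy_measurements(), ["Z"]),
        )
        assert fit.beta[0] == pytest.approx(toy_oracle_beta, abs=1e-4)

    def test_null_effect_recovery(self):
        """With treatment independent of Z the coefficient is ~0."""
        cfg = DGMConfig(n_patients=600, seed=21, betaT_true=0.0)
        pop = generate_population(cfg)
        fit = fit_denominator_model(pop.episodes, PopulationCovariates(pop))
        assert abs(fit.beta[0]) < 3 * fit.se[0]

    def test_no_treatment_raises(self):
        eps = toy_episodes(as_treatment=True)
        eps["treated"] = 0
        with pytest.raises(RuntimeError):
            fit_denominator_model(eps, LongTableCovariates(toy_measurements(), ["Z"]))


class TestNumeratorModel:
    def test_null_model_is_per_section_nelson_aalen(self, pop500, default_cfg):
        """With no stabilizer covariates, the numerator reduces to the
        per-cross-section nonparametric treatment-free estimate."""
        cov = PopulationCovariates(pop500)
        st = build_never_treated_stack(
            pop500.episodes.iloc[:200], cov, np.array([1.0, 2.0]), 3.0
        )
        fit = fit_numerator_model(st, CovariateRoles(patient=[]))
        for k in st.rows["k"].unique():
            grp = st.rows[st.rows["k"] == k]
            t = grp["u_stop"].to_numpy()
            d = grp["artificial_censor"].to_numpy()
            for te in np.sort(t[d == 1]):
                atrisk = (t >= te).sum()
                inc = fit.baseline[k].increments[
                    np.searchsorted(fit.baseline[k].times, te)
                ]
                assert inc == pytest.approx(1.0 / atrisk)

    def test_stratified_duplicate_equals_single(self, stacks500, default_cfg):
        rows = stacks500.never.rows
        one = rows[rows["k"] == rows["k"].value_counts().idxmax()].copy()
        from seqbenefit.cohort import CrossSectionStack

        single = fit_numerator_model(CrossSectionStack(one, "never_treated", 3.0))
        two = pd.concat([one, one.assign(k=one["k"] + 1000)], ignore_index=True)
        double = fit_numerator_model(CrossSectionStack(two, "never_treated", 3.0))
        assert np.allclose(single.beta, double.beta, atol=1e-10)


class TestTreatedProbabilityModel:
    def test_cloglog_identity(self):
        m = ClogLogModel(np.array([np.log(np.log(2.0))]), [], [])
        df = pd.DataFrame(index=range(3))
        assert np.allclose(m.predict(df), 0.5)

    def test_link_range(self):
        lo = ClogLogModel(np.array([-40.0]), [], []).predict(pd.DataFrame(index=[0]))
        hi = ClogLogModel(np.array([+5.0]), [], []).predict(pd.DataFrame(index=[0]))
        assert lo[0] == pytest.approx(0.0, abs=1e-12)
        assert hi[0] == pytest.approx(1.0, abs=1e-12)

    def test_parameter_recovery(self):
        """Known cloglog coefficients recovered within 3 SE at n = 5000."""
        rng = np.random.default_rng(8)
        n = 5000
        df = pd.DataFrame({"Z": rng.normal(size=n), "Zstar": rng.normal(size=n)})
        truth = np.array([-2.0, 0.8, -0.5, 0.3])
        eta = truth[0] + truth[1] * df["Z"] + truth[2] * df["Zstar"] + truth[3] * df["Z"] * df["Zstar"]
        df["treated_flag"] = (rng.random(n) < 1 - np.exp(-np.exp(eta))).astype(int)
        m = fit_treated_probability_model(df)
        assert m.se is not None
        assert np.all(np.abs(m.params - truth) < 3 * m.se)


class TestWeights:
    def test_cumhaz_arithmetic_oracle(self):
        w = stabilized_weight_from_cumhaz([0.0, 0.1, 0.2], [0.0, 0.3, 0.5])
        assert np.allclose(w, [1.0, np.exp(0.2), np.exp(0.3)])

    def test_identical_models_give_unit_weights(self):
        """All subjects entering at s=0 with one cross-section at date 0 and
        constant covariates: numerator and denominator are the same model on
        the same data, so every never-treated weight is exactly 1."""
        rng = np.random.default_rng(4)
        n = 40
        z = rng.normal(size=n)
        treat = rng.random(n) < 0.5
        times = rng.uniform(0.2, 2.8, n)
        eps = pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "s_entry": 0.0,
                "X": times,
                "delta": (~treat).astype(int),
                "treated": treat.astype(int),
                "censor_admin": 0,
                "T": np.where(treat, times, np.nan),
                "Zstar": np.where(treat, rng.normal(size=n), np.nan),
                "post_time": np.where(treat, 0.5, np.nan),
                "post_delta": np.where(treat, 1, 0),
            }
        )
        meas = pd.DataFrame({"patient_id": np.arange(n), "t": 0.0, "Z": z})
        cov = LongTableCovariates(meas, ["Z"])
        never = build_never_treated_stack(eps, cov, np.array([0.0]), 3.0, eligibility_threshold=-np.inf)
        from seqbenefit.cohort import build_treated_stack
        from seqbenefit.simulate import OfferStream

        dates = np.round(np.arange(0, 9, 0.01), 10)
        stream = OfferStream(dates[::4], dates, pd.DataFrame(
            {"date_idx": np.arange(dates.size), "date": dates, "Zstar": 0.0, "patient_id": -1}
        ))
        # round treatment times onto the grid so the treated stack maps
        eps_r = eps.copy()
        treated_stack = build_treated_stack(eps_r, cov, stream, 3.0, eligibility_threshold=-np.inf)
        den = fit_denominator_model(eps, cov)
        num = fit_numerator_model(never)
        snaps = pd.DataFrame({"Z": z, "Zstar": 0.0, "treated_flag": treat.astype(int), "date_idx": 0})
        prob = fit_treated_probability_model(snaps)
        from seqbenefit.weights import WeightModelSet, estimate_lambda1_num

        models = WeightModelSet(
            denominator=den, numerator=num, treated_prob=prob,
            lambda1_num=estimate_lambda1_num(snaps),
            roles=CovariateRoles(), options=WeightOptions(),
        )
        ws = compute_weights(never, treated_stack, models, cov)
        assert np.allclose(ws.never_rows["weight"], 1.0, atol=1e-9)

    def test_treated_weight_is_probability_ratio(self, pop500, default_cfg, stacks500):
        models = fit_weight_models(stacks500, pop500.episodes, default_cfg)
        ws = compute_weights(stacks500.never, stacks500.treated, models, stacks500.covariates)
        tr = ws.treated_rows
        phat = models.treated_prob.predict(tr)
        lam = models.lambda1_num_at(tr["k"].to_numpy())
        assert np.allclose(tr["weight"], lam / phat)
        # direct ratio example: lambda=0.02, phat=0.04 -> weight 0.5
        assert stabilized_weight_from_cumhaz(0.0, 0.0) * 0.02 / 0.04 == pytest.approx(0.5)

    def test_capping_properties(self, pop500, default_cfg, stacks500):
        models = fit_weight_models(stacks500, pop500.episodes, default_cfg)
        uncapped = compute_weights(stacks500.never, stacks500.treated, models, stacks500.covariates)
        models_c1 = models
        models_c1.options = WeightOptions(cap_quantile=1.0)
        identity = compute_weights(stacks500.never, stacks500.treated, models_c1, stacks500.covariates)
        assert np.allclose(uncapped.never_rows["weight"], identity.never_rows["weight"])
        prev_max = np.inf
        for q in (0.9999, 0.99, 0.9):
            models.options = WeightOptions(cap_quantile=q)
            capped = compute_weights(stacks500.never, stacks500.treated, models, stacks500.covariates)
            allw = np.concatenate([capped.never_rows["weight"], capped.treated_rows["weight"]])
            pooled = np.concatenate([uncapped.never_rows["weight"], uncapped.treated_rows["weight"]])
            assert allw.max() <= np.quantile(pooled, q) + 1e-12
            assert allw.max() <= prev_max + 1e-12
            prev_max = allw.max()

    def test_positivity_violation_raises(self, pop500, default_cfg, stacks500):
        models = fit_weight_models(stacks500, pop500.episodes, default_cfg)
        models.treated_prob.params = models.treated_prob.params * 0 - 1e4
        with pytest.raises(PositivityError):
            compute_weights(stacks500.never, stacks500.treated, models, stacks500.covariates)
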