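"""Data-generating mechanism: OU process, event draws, ground truth."""

import numpy as np
import pytest
import scipy.integrate as si
from scipy import stats

from seqbenefit.config import DGMConfig
from seqbenefit.simulate import (
    HazardSpec,
    PatientTrajectory,
    draw_event_time,
    draw_posttreatment_time,
    generate_population,
    simulate_covariate_path,
    simulate_ou_path,
    true_rmst0,
    true_rmst0_batch,
    true_rmst1,
)

CFG = DGMConfig(n_patients=50, seed=0)

# frozen quadrature-oracle values (scipy.integrate.quad, computed once)
RMST0_Z0 = si.quad(lambda u: np.exp(-0.1 * u * u), 0, 3)[0]  # 2.29885...
RMST1_00 = si.quad(lambda u: np.exp(-0.0375 * u * u), 0, 3)[0]  # 2.69410...


class TestOUProcess:
    def test_zero_noise_is_identically_zero(self):
        grid = np.arange(0, 5.01, 0.01)
        p = simulate_ou_path(0.3, 0.0, grid, 100, np.random.default_rng(1))
        assert np.all(p == 0.0)

    def test_single_step_identity(self):
        """One update equals xi*exp(-theta dt) + the drawn noise exactly."""
        theta, sigma, dt = 0.1, 0.0045, 0.01
        rng = np.random.default_rng(5)
        grid = np.array([0.0, dt])
        p = simulate_ou_path(theta, sigma, grid, 1, rng)
        a = np.exp(-theta * dt)
        sd = sigma * np.sqrt((1 - a * a) / (2 * theta))
        eps = sd * np.random.default_rng(5).standard_normal((2, 1))
        assert p[0] == pytest.approx(eps[0, 0], rel=1e-12)  # burn-in step from 0
        assert p[1] == pytest.approx(a * eps[0, 0] + eps[1, 0], rel=1e-12)

    def test_stationary_moments(self):
        """10^5-step path: mean within 3 SE of 0, variance within 10% of
        sigma^2/(2 theta)."""
        theta, sigma = 0.1, 0.0045
        grid = np.arange(0, 1000.001, 0.01)
        p = simulate_ou_path(theta, sigma, grid, 100, np.random.default_rng(0))
        target = sigma**2 / (2 * theta)
        assert abs(p.var() / target - 1) < 0.10
        n_eff = (grid[-1] * theta) / 2  # decorrelation time 1/theta
        se = np.sqrt(target / n_eff)
        assert abs(p.mean()) < 3 * se

    def test_invalid_theta_raises(self):
        with pytest.raises(ValueError):
            simulate_ou_path(0.0, 1.0, np.arange(3.0), 10, np.random.default_rng(0))


class TestCovariatePath:
    def test_constant_and_linear(self):
        grid = np.arange(0, 3.01, 0.01)
        zero = np.zeros(grid.size)
        assert np.allclose(simulate_covariate_path(2.0, 0.0, zero, grid), 2.0)
        z = simulate_covariate_path(0.0, 0.5, zero, grid)
        assert z[np.searchsorted(grid, 2.0)] == pytest.approx(1.0)

    def test_residual_linearity(self, pop500):
        """Z(t) - xi(t) is exactly linear in t with slope eta."""
        i = 3
        resid = pop500.z_paths[i] - pop500.ou_paths[i]
        slopes = np.diff(resid) / np.diff(pop500.grid)
        assert np.allclose(slopes, pop500.eta[i], atol=1e-9)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            simulate_covariate_path(0.0, 0.0, np.zeros(5), np.arange(4.0))


class TestEventDraws:
    def test_exponential_inversion(self):
        grid = np.arange(0, 13.01, 0.01)
        t = draw_event_time(HazardSpec(("constant", 1.0)), np.zeros(grid.size), grid, u=0.5)
        assert t == pytest.approx(np.log(2), abs=1e-12)

    def test_quadratic_cumhaz_inversion(self):
        """h0 with Z=0: Lambda(t) = 0.1 t^2, so U = e^-0.9 gives t = 3."""
        cfg = CFG
        t = draw_event_time(
            HazardSpec(("linear", 0.2), coef=1.5), np.zeros(1301), cfg.grid, u=np.exp(-0.9)
        )
        assert t == pytest.approx(3.0, abs=1e-12)

    def test_negative_rate_raises(self):
        with pytest.raises(ValueError):
            HazardSpec(("linear", -1.0))

    def test_survival_matches_closed_form(self):
        """With Z = z constant, the draws follow S(t) = exp(-0.1 t^2 e^{1.5 z})
        (Kolmogorov-Smirnov distance < 0.02 at n = 10^4)."""
        z = 0.4
        cfg = CFG
        rng = np.random.default_rng(2)
        spec = HazardSpec(("linear", 0.2), coef=1.5)
        zp = np.full(cfg.grid.size, z)
        draws = np.array(
            [draw_event_time(spec, zp, cfg.grid, u=u) for u in rng.random(10_000)]
        )
        cdf = lambda t: 1 - np.exp(-0.1 * t**2 * np.exp(1.5 * z))
        ks = stats.kstest(draws, cdf)
        assert ks.statistic < 0.02

    def test_posttreatment_closed_form_and_f(self):
        cfg = CFG
        assert np.allclose(cfg.f_effect([-1, 0, 0.3, 1]), [1.2, 0.0, -0.6, -1.2])
        v = draw_posttreatment_time(0.0, 0.0, cfg, u=np.exp(-0.0375 * 4))
        assert v == pytest.approx(2.0, abs=1e-9)

    def test_null_offer_effect_invariance(self):
        """With gamma1 = 0 the residual time ignores the offer quality."""
        cfg = CFG.model_copy(update={"gamma1_true": 0.0})
        a = draw_posttreatment_time(0.3, -2.0, cfg, u=0.42)
        b = draw_posttreatment_time(0.3, 5.0, cfg, u=0.42)
        assert a == b


class TestGeneratePopulation:
    def test_no_treatment_limit(self):
        cfg = DGMConfig(n_patients=200, seed=4, lambdaT_constant=1e-12)
        pop = generate_population(cfg)
        assert pop.treated.sum() == 0
        assert np.all(pop.delta | pop.censor_admin)

    def test_degenerate_window(self):
        cfg = DGMConfig(n_patients=100, seed=4, window_end=1e-4, cs_calendar_end=1e-4)
        pop = generate_population(cfg)
        assert pop.censor_admin.all()
        assert pop.X.max() < 1e-4

    def test_treated_fraction_interior_and_confounded(self):
        """Fraction treated is strictly inside (0,1); betaT shifts treatment
        toward high-Z patients (mean Z at treatment rises with betaT)."""
        p0 = generate_population(DGMConfig(n_patients=1500, seed=3, betaT_true=0.0))
        p2 = generate_population(DGMConfig(n_patients=1500, seed=3, betaT_true=2.0))
        for p in (p0, p2):
            assert 0.0 < p.treated.mean() < 1.0
        zT0 = p0.z_at(np.flatnonzero(p0.treated), p0.T_latent[p0.treated])
        zT2 = p2.z_at(np.flatnonzero(p2.treated), p2.T_latent[p2.treated])
        assert zT2.mean() > zT0.mean() + 0.2

    def test_seed_reproducibility_bit_identical(self):
        cfg = DGMConfig(n_patients=120, seed=9)
        a, b = generate_population(cfg), generate_population(cfg)
        assert np.array_equal(a.z_paths, b.z_paths)
        assert a.episodes.equals(b.episodes)
        assert a.offer_stream.offers.equals(b.offer_stream.offers)

    def test_episode_cause_partition(self, pop500):
        """Exactly one of death / treatment / administrative censoring
        explains each observed time."""
        total = pop500.delta.astype(int) + pop500.treated.astype(int) + pop500.censor_admin.astype(int)
        assert np.all(total == 1)
        assert np.all(pop500.X > 0)
        assert np.isfinite(pop500.Zstar[pop500.treated]).all()
        assert np.isnan(pop500.Zstar[~pop500.treated]).all()

    def test_offer_stream_carries_delivered_zstar(self, pop500):
        offers = pop500.offer_stream.offers
        delivered = offers[offers["patient_id"] >= 0]
        for _, row in delivered.head(10).iterrows():
            assert row["Zstar"] == pop500.Zstar[int(row["patient_id"])]
        # every fine date has at least one offer
        assert set(offers["date_idx"]) == set(range(pop500.offer_stream.dates_fine.size))

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            DGMConfig(n_patients=0)


class TestTruth:
    def test_rmst0_zero_covariate(self):
        tr = PatientTrajectory(0, 0.0, np.zeros(1301), np.zeros(1301), 1.0, 1.0)
        assert true_rmst0(tr, 0.0, CFG) == pytest.approx(RMST0_Z0, abs=1e-3)

    def test_rmst0_no_mortality(self):
        cfg = CFG.model_copy(update={"lambda0_constant": 1e-300})
        tr = PatientTrajectory(0, 0.0, np.zeros(1301), np.zeros(1301), 1.0, 1.0)
        assert true_rmst0(tr, 0.0, cfg) == pytest.approx(3.0, abs=1e-9)

    def test_rmst0_grid_refinement(self, pop500):
        idx = np.arange(10)
        sk = np.linspace(0.0, 2.0, 10)
        coarse = true_rmst0_batch(pop500, idx, sk)
        fine = true_rmst0_batch(pop500, idx, sk, u_step=0.005)
        assert np.max(np.abs(coarse - fine)) < 1e-4

    def test_rmst1_values_and_monotonicity(self):
        assert true_rmst1(0.0, 0.0, CFG) == pytest.approx(RMST1_00, abs=1e-3)
        r = true_rmst1(0.5, np.array([-1.0, 0.0, 1.0]), CFG)
        assert np.all(np.diff(r) < 0)  # better offer quality here raises hazard

    def test_rmst_bounds(self, pop500):
        idx = np.arange(50)
        sk = np.full(50, 1.5)
        r0 = true_rmst0_batch(pop500, idx, sk)
        r1 = true_rmst1(pop500.z_at(idx, sk), np.zeros(50), pop500.config)
        assert np.all((r0 >= 0) & (r0 <= 3.0))
        assert np.all((r1 >= 0) & (r1 <= 3.0))

    def test_identical_hazards_zero_benefit(self):
        """If both strategies share one hazard, benefit is zero."""
        cfg = CFG.model_copy(
            update={"lambda1_slope": 0.2, "f_linear": True, "f_slope": 1.5, "gamma1_true": 0.0}
        )
        z = np.full(1301, 0.7)
        tr = PatientTrajectory(0, 0.0, z, np.zeros(1301), 1.0, 1.0)
        r0 = true_rmst0(tr, 0.0, cfg)
        r1 = true_rmst1(0.7, 0.0, cfg)
        assert r1 == pytest.approx(r0, abs=1e-6)

    def test_short_path_raises(self, pop500):
        with pytest.raises(ValueError):
            true_rmst0_batch(pop500, [0], [12.5])
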