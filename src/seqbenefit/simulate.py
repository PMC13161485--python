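"""Synthetic waiting-list populations and their ground-truth survival.

The generator produces, for each patient, a latent health trajectory
Z(t) = mu + eta*t + xi(t) on a fine time grid (xi is a mean-zero
Ornstein-Uhlenbeck process advanced with its exact Gaussian transition), the
potential never-treated death time D0, the latent treatment time T, and --
for patients observed treated -- a treatment-quality covariate Z* and the
residual post-treatment death time.  Event times are drawn by
inverse-transform sampling with the cumulative hazard accumulated exactly
over grid cells, so the draws are continuous (not grid-rounded).

Ground-truth restricted mean survival times (never-treated and treated with
a given offer) are computed by numerical integration of the same hazards and
serve as the reference values in the calibration study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import DGMConfig

__all__ = [
    "HazardSpec",
    "PatientTrajectory",
    "OfferStream",
    "Population",
    "simulate_ou_path",
    "simulate_covariate_path",
    "draw_event_time",
    "draw_posttreatment_time",
    "generate_population",
    "true_rmst0",
    "true_rmst1",
    "true_benefit",
]


# ---------------------------------------------------------------------------
# hazard specification and inverse-transform sampling


@dataclass(frozen=True)
class HazardSpec:
    """Proportional-hazards specification lambda(t) * exp(coef * g(z)).

    ``baseline`` is ``("linear", c)`` for lambda(t) = c*t or
    ``("constant", c)`` for lambda(t) = c.  ``transform`` maps the covariate
    into the linear predictor (identity if None).
    """

    baseline: tuple[str, float]
    coef: float = 0.0
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self):
        kind, c = self.baseline
        if kind not in ("linear", "constant"):
            raise ValueError(f"unknown baseline kind {kind!r}")
        if c < 0:
            raise ValueError("baseline rate/slope must be >= 0")

    def cell_integrals(self, grid: np.ndarray) -> np.ndarray:
        """Exact integral of the baseline over each grid cell."""
        kind, c = self.baseline
        if kind == "linear":
            return 0.5 * c * (grid[1:] ** 2 - grid[:-1] ** 2)
        return c * np.diff(grid)

    def lp(self, z: np.ndarray) -> np.ndarray:
        g = z if self.transform is None else self.transform(z)
        return self.coef * np.asarray(g, dtype=float)


def _draw_event_times(
    spec: HazardSpec, z_paths: np.ndarray, grid: np.ndarray, U: np.ndarray
) -> np.ndarray:
    """Vectorized inverse-transform draw; +inf if no event by grid end.

    ``z_paths`` is (n, G) with the covariate piecewise constant on cells
    (value of cell i is the value at its left node).
    """
    z_paths = np.atleast_2d(z_paths)
    fac = np.exp(spec.lp(z_paths[:, :-1]))  # (n, G-1)
    base = spec.cell_integrals(grid)  # (G-1,)
    cum = np.concatenate(
        [np.zeros((fac.shape[0], 1)), np.cumsum(fac * base, axis=1)], axis=1
    )
    E = -np.log(np.asarray(U, dtype=float))
    j = (cum < E[:, None]).sum(axis=1) - 1  # cell index with the crossing
    out = np.full(z_paths.shape[0], np.inf)
    hit = j < grid.size - 1
    jh = j[hit]
    rem = (E[hit] - cum[hit, jh]) / fac[hit, jh]
    kind, c = spec.baseline
    if kind == "linear":
        out[hit] = np.sqrt(grid[jh] ** 2 + 2.0 * rem / c)
    else:
        out[hit] = grid[jh] + rem / c
    return out


def draw_event_time(hazard_spec: HazardSpec, z_path, grid, rng=None, u=None) -> float:
    """Draw one event time by inverse-transform sampling.

    Either ``rng`` (a Generator) or ``u`` (an explicit uniform variate, for
    deterministic checks) must be given.
    """
    if u is None:
        if rng is None:
            raise ValueError("provide rng or u")
        u = rng.random()
    return float(
        _draw_event_times(hazard_spec, np.asarray(z_path, float), np.asarray(grid, float), np.array([u]))[0]
    )


def draw_posttreatment_time(zT, zstar, config: DGMConfig, rng=None, u=None) -> float:
    """Residual post-treatment death time D1 - T.

    The linear predictor f(Z(T)) + gamma1 * Z* is time-fixed, so the draw
    reduces to inverting Lambda(v) = (lambda1_slope/2) v^2 e^{lp}.
    """
    if not (np.isfinite(zT) and np.isfinite(zstar)):
        raise ValueError("zT and zstar must be finite")
    lp = float(config.f_effect(zT) + config.gamma1_true * zstar)
    spec = HazardSpec(("linear", config.lambda1_slope), coef=1.0)
    grid = config.grid
    z_const = np.full(grid.size, lp)
    return draw_event_time(spec, z_const, grid, rng=rng, u=u)


# ---------------------------------------------------------------------------
# covariate process


def simulate_ou_paths(theta, sigma, grid, burnin_steps, rng, n) -> np.ndarray:
    """Exact-transition OU paths, (n, G); burn-in from 0 at step grid_dt."""
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    dts = np.diff(grid)
    if not np.allclose(dts, dts[0]):
        raise ValueError("grid must be evenly spaced")
    dt = dts[0]
    a = np.exp(-theta * dt)
    sd = sigma * np.sqrt((1.0 - a * a) / (2.0 * theta))
    steps = burnin_steps + grid.size - 1
    eps = sd * rng.standard_normal((steps, n))
    # xi_{k+1} = a xi_k + eps_k from xi = 0: a linear recursive filter
    y = lfilter([1.0], [1.0, -a], eps, axis=0)
    if burnin_steps > 0:
        path = y[burnin_steps - 1 :]
    else:
        path = np.concatenate([np.zeros((1, n)), y], axis=0)
    return path.T.copy()


def simulate_ou_path(theta, sigma, grid, burnin_steps, rng) -> np.ndarray:
    """Single OU path on ``grid`` (exact Gaussian transition)."""
    return simulate_ou_paths(theta, sigma, grid, burnin_steps, rng, 1)[0]


def simulate_covariate_path(mu, eta, ou_path, grid) -> np.ndarray:
    """Z(t) = mu + eta*t + xi(t), pointwise on the grid."""
    ou_path = np.asarray(ou_path, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if ou_path.shape[-1] != grid.size:
        raise ValueError("ou_path and grid are not aligned")
    mu = np.asarray(mu, dtype=float)
    eta = np.asarray(eta, dtype=float)
    return mu[..., None] + eta[..., None] * grid + ou_path


# ---------------------------------------------------------------------------
# population containers


@dataclass
class PatientTrajectory:
    """Latent record of one simulated subject (all potential outcomes)."""

    patient_id: int
    s_entry: float
    z_path: np.ndarray
    ou_path: np.ndarray
    D0_time: float
    T_time: float
    Zstar: float | None = None
    D1_residual: float | None = None


@dataclass
class OfferStream:
    """Treatment offers indexed by calendar date.

    ``offers`` has one row per offer: ``date_idx`` (index into
    ``dates_fine``), ``date``, ``Zstar`` and ``patient_id`` of the delivered
    treatment (-1 for synthetic offers at dates without a treatment).  Dates
    at which several treatments occurred carry several rows and are treated
    as separate cross-sections downstream.
    """

    dates_coarse: np.ndarray
    dates_fine: np.ndarray
    offers: pd.DataFrame

    def zstar_primary(self) -> np.ndarray:
        """One Z* per fine date (the first offer at each date)."""
        first = self.offers.groupby("date_idx", sort=True)["Zstar"].first()
        out = np.empty(self.dates_fine.size)
        out[first.index.values] = first.values
        return out


@dataclass
class Population:
    """A simulated cohort: latent trajectories plus observed episodes."""

    config: DGMConfig
    grid: np.ndarray
    s_entry: np.ndarray
    mu: np.ndarray
    eta: np.ndarray
    ou_paths: np.ndarray
    z_paths: np.ndarray
    D0: np.ndarray
    T_latent: np.ndarray
    X: np.ndarray
    delta: np.ndarray
    treated: np.ndarray
    censor_admin: np.ndarray
    Zstar: np.ndarray  # nan unless observed treated
    D1_residual: np.ndarray  # nan unless observed treated
    post_time: np.ndarray  # observed residual follow-up after T (nan if untreated)
    post_delta: np.ndarray  # death indicator for post_time
    offer_stream: OfferStream
    episodes: pd.DataFrame = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.s_entry.size

    def trajectory(self, i: int) -> PatientTrajectory:
        tr = bool(self.treated[i])
        return PatientTrajectory(
            patient_id=i,
            s_entry=float(self.s_entry[i]),
            z_path=self.z_paths[i],
            ou_path=self.ou_paths[i],
            D0_time=float(self.D0[i]),
            T_time=float(self.T_latent[i]),
            Zstar=float(self.Zstar[i]) if tr else None,
            D1_residual=float(self.D1_residual[i]) if tr else None,
        )

    def z_at(self, idx, times) -> np.ndarray:
        """Z for patients ``idx`` at follow-up times ``times`` (grid LOCF)."""
        idx = np.asarray(idx, dtype=int)
        t = np.asarray(times, dtype=float)
        j = np.clip(
            np.floor(t / self.config.grid_dt + 1e-9).astype(int),
            0,
            self.grid.size - 1,
        )
        return self.z_paths[idx, j]

    def measurements_long(self, round_times: bool = False) -> pd.DataFrame:
        """Long-format covariate table (patient_id, t, Z), truncated at X."""
        recs = []
        dt = self.config.grid_dt
        for i in range(self.n):
            m = int(np.floor(self.X[i] / dt + 1e-9)) + 1
            recs.append(
                pd.DataFrame(
                    {
                        "patient_id": i,
                        "t": self.grid[:m],
                        "Z": self.z_paths[i, :m],
                    }
                )
            )
        out = pd.concat(recs, ignore_index=True)
        if round_times:
            out["t"] = out["t"].round(2)
        return out


def _round_to_fine(dates, spacing):
    """Nearest fine-grid index, ties toward the earlier date."""
    return np.ceil(np.asarray(dates) / spacing - 0.5).astype(int)


def generate_population(config: DGMConfig, rng=None) -> Population:
    """Simulate a full population (latent world + observed episodes + offers).

    Fully reproducible: with ``rng=None`` the stream is seeded from
    ``config.seed``; draw order is fixed.
    """
    if config.n_patients <= 0:
        raise ValueError("n_patients must be > 0")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_patients
    grid = config.grid

    mu = config.mu_sd * rng.standard_normal(n)
    eta = config.eta_sd * rng.standard_normal(n)
    ou = simulate_ou_paths(
        config.ou_theta, config.ou_sigma, grid, config.ou_burnin_steps, rng, n
    )
    z = simulate_covariate_path(mu, eta, ou, grid)

    s_entry = config.window_end * rng.random(n)
    U_d0 = rng.random(n)
    U_t = rng.random(n)
    zstar_all = rng.standard_normal(n)
    U_d1 = rng.random(n)

    if config.lambda0_constant is not None:
        h0 = HazardSpec(("constant", config.lambda0_constant), coef=config.beta0_true)
    else:
        h0 = HazardSpec(("linear", config.lambda0_slope), coef=config.beta0_true)
    if config.lambdaT_constant is not None:
        hT = HazardSpec(("constant", config.lambdaT_constant), coef=config.betaT_true)
    else:
        hT = HazardSpec(("linear", config.lambdaT_slope), coef=config.betaT_true)
    D0 = _draw_event_times(h0, z, grid, U_d0)
    T = _draw_event_times(hT, z, grid, U_t)

    C = config.window_end - s_entry
    X = np.minimum(np.minimum(D0, T), C)
    treated = (T == X) & (T < D0)
    delta = (D0 == X) & ~treated
    censor_admin = ~treated & ~delta

    Zstar = np.where(treated, zstar_all, np.nan)
    zT = np.take_along_axis(
        z, np.clip(np.floor(np.where(treated, T, 0.0) / config.grid_dt + 1e-9), 0, grid.size - 1).astype(int)[:, None], axis=1
    )[:, 0]
    lp1 = config.f_effect(zT) + config.gamma1_true * zstar_all
    # residual time: invert Lambda(v) = (lambda1_slope/2) v^2 e^{lp}
    D1_res_all = np.sqrt(
        -np.log(U_d1) / (0.5 * config.lambda1_slope * np.exp(lp1))
    )
    D1_residual = np.where(treated, D1_res_all, np.nan)
    res_censor = np.where(treated, C - T, np.nan)
    post_time = np.where(treated, np.minimum(D1_residual, res_censor), np.nan)
    post_delta = np.where(treated, D1_residual <= res_censor, False)

    # offer stream: fresh N(0,1) per fine date, overwritten by the Z* of
    # treatments whose calendar date rounds to that fine date
    dates_fine = config.dates_fine()
    dates_coarse = config.dates_coarse()
    zstar_dates = rng.standard_normal(dates_fine.size)
    offer_rows = [
        pd.DataFrame(
            {
                "date_idx": np.arange(dates_fine.size),
                "date": dates_fine,
                "Zstar": zstar_dates,
                "patient_id": -1,
            }
        )
    ]
    t_cal = s_entry + T
    tr_idx = np.flatnonzero(treated)
    didx = _round_to_fine(t_cal[tr_idx], config.cs_spacing_fine)
    ok = (didx >= 0) & (didx < dates_fine.size)
    delivered = pd.DataFrame(
        {
            "date_idx": didx[ok],
            "date": dates_fine[didx[ok]],
            "Zstar": Zstar[tr_idx[ok]],
            "patient_id": tr_idx[ok],
        }
    )
    base = offer_rows[0]
    base = base[~base["date_idx"].isin(delivered["date_idx"])]
    offers = (
        pd.concat([base, delivered], ignore_index=True)
        .sort_values(["date_idx", "patient_id"])
        .reset_index(drop=True)
    )
    stream = OfferStream(dates_coarse=dates_coarse, dates_fine=dates_fine, offers=offers)

    episodes = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "s_entry": s_entry,
            "X": X,
            "delta": delta.astype(int),
            "treated": treated.astype(int),
            "censor_admin": censor_admin.astype(int),
            "T": np.where(treated, T, np.nan),
            "Zstar": Zstar,
            "post_time": post_time,
            "post_delta": post_delta.astype(int),
        }
    )

    return Population(
        config=config,
        grid=grid,
        s_entry=s_entry,
        mu=mu,
        eta=eta,
        ou_paths=ou,
        z_paths=z,
        D0=D0,
        T_latent=T,
        X=X,
        delta=delta,
        treated=treated,
        censor_admin=censor_admin,
        Zstar=Zstar,
        D1_residual=D1_residual,
        post_time=post_time,
        post_delta=post_delta,
        offer_stream=stream,
        episodes=episodes,
    )


# ---------------------------------------------------------------------------
# ground truth


def _h0_spec(config: DGMConfig) -> HazardSpec:
    if config.lambda0_constant is not None:
        return HazardSpec(("constant", config.lambda0_constant), coef=config.beta0_true)
    return HazardSpec(("linear", config.lambda0_slope), coef=config.beta0_true)


def _cumhaz0_nodes(z_paths: np.ndarray, config: DGMConfig) -> np.ndarray:
    """Exact cumulative untreated-death hazard at grid nodes, (n, G)."""
    fac = np.exp(config.beta0_true * z_paths[:, :-1])
    base = _h0_spec(config).cell_integrals(config.grid)
    return np.concatenate(
        [np.zeros((z_paths.shape[0], 1)), np.cumsum(fac * base, axis=1)], axis=1
    )


def _cumhaz0_at(nodes, z_paths, times, config: DGMConfig, row_idx):
    """Lambda0(t) for arbitrary times; exact within the containing cell."""
    grid = config.grid
    t = np.asarray(times, dtype=float)
    j = np.clip(np.floor(t / config.grid_dt + 1e-9).astype(int), 0, grid.size - 2)
    if config.lambda0_constant is not None:
        cell = config.lambda0_constant * (t - grid[j])
    else:
        cell = 0.5 * config.lambda0_slope * (t**2 - grid[j] ** 2)
    partial = np.exp(config.beta0_true * z_paths[row_idx, j]) * cell
    return nodes[row_idx, j] + partial


def true_rmst0_batch(pop: Population, patient_idx, Sk, u_step: float | None = None) -> np.ndarray:
    """True never-treated RMST over the horizon for (patient, Sk) pairs.

    Integrates exp(-int_{Sk}^{Sk+u} h0(s|Z(s)) ds) over u in [0, L]: the
    inner integral is accumulated exactly per grid cell, the outer one uses
    the trapezoid rule on the u grid.
    """
    config = pop.config
    patient_idx = np.asarray(patient_idx, dtype=int)
    Sk = np.asarray(Sk, dtype=float)
    if np.any(Sk < 0):
        raise ValueError("Sk must be >= 0")
    if np.any(Sk + config.horizon_L > pop.grid[-1] + 1e-9):
        raise ValueError("covariate path does not cover [Sk, Sk+L]")
    du = u_step or config.grid_dt
    u = np.arange(0.0, config.horizon_L + du / 2, du)
    nodes = _cumhaz0_nodes(pop.z_paths, config)
    out = np.empty(patient_idx.size)
    chunk = max(1, int(2e6 // u.size))
    for lo in range(0, patient_idx.size, chunk):
        hi = min(lo + chunk, patient_idx.size)
        pi = patient_idx[lo:hi]
        sk = Sk[lo:hi]
        tt = sk[:, None] + u[None, :]
        rows = np.repeat(pi, u.size)
        lam = _cumhaz0_at(nodes, pop.z_paths, tt.ravel(), config, rows).reshape(
            hi - lo, u.size
        )
        surv = np.exp(-(lam - lam[:, :1]))
        out[lo:hi] = np.trapezoid(surv, dx=du, axis=1)
    return out


def true_rmst0(trajectory_or_pop, Sk, config: DGMConfig | None = None) -> float:
    """Scalar convenience wrapper around :func:`true_rmst0_batch`."""
    if isinstance(trajectory_or_pop, PatientTrajectory):
        tr = trajectory_or_pop
        pop = _single_patient_pop(tr, config)
        return float(true_rmst0_batch(pop, [0], [Sk])[0])
    raise TypeError("pass a PatientTrajectory (use true_rmst0_batch for cohorts)")


def _single_patient_pop(tr: PatientTrajectory, config: DGMConfig) -> Population:
    z = tr.z_path[None, :]
    dummy = np.zeros(1)
    return Population(
        config=config,
        grid=config.grid,
        s_entry=np.array([tr.s_entry]),
        mu=dummy,
        eta=dummy,
        ou_paths=tr.ou_path[None, :],
        z_paths=z,
        D0=np.array([tr.D0_time]),
        T_latent=np.array([tr.T_time]),
        X=dummy,
        delta=dummy.astype(bool),
        treated=dummy.astype(bool),
        censor_admin=dummy.astype(bool),
        Zstar=np.array([np.nan]),
        D1_residual=np.array([np.nan]),
        post_time=np.array([np.nan]),
        post_delta=dummy.astype(bool),
        offer_stream=OfferStream(np.array([]), np.array([]), pd.DataFrame()),
        episodes=pd.DataFrame(),
    )


def true_rmst1(zK, zstar, config: DGMConfig, u_step: float | None = None) -> np.ndarray:
    """True post-treatment RMST for covariate zK and offer quality zstar.

    S1(u) = exp(-(lambda1_slope/2) u^2 e^{f(zK) + gamma1*zstar}); integrated
    by the trapezoid rule on the u grid.
    """
    zK = np.asarray(zK, dtype=float)
    zstar = np.asarray(zstar, dtype=float)
    lp = config.f_effect(zK) + config.gamma1_true * zstar
    du = u_step or config.grid_dt
    u = np.arange(0.0, config.horizon_L + du / 2, du)
    surv = np.exp(
        -0.5 * config.lambda1_slope * u[None, :] ** 2 * np.exp(lp)[..., None]
    )
    res = np.trapezoid(surv, dx=du, axis=-1)
    return res if res.ndim else float(res)


def true_benefit(pop: Population, patient_idx, Sk, zK, zstar) -> np.ndarray:
    """True conditional survival benefit RMST1 - RMST0 for given offers."""
    r0 = true_rmst0_batch(pop, patient_idx, Sk)
    r1 = true_rmst1(zK, zstar, pop.config)
    return r1 - r0
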