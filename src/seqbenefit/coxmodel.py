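"""Weighted Cox proportional-hazards engine for counting-process data.

This module implements partial-likelihood estimation for data in start-stop
(counting-process) layout with case weights, strata, and clustered sandwich
standard errors, together with the Breslow estimator of the cumulative
baseline hazard.  Ties are handled with the Breslow approximation, matching
the Breslow baseline used when weights are built from fitted cumulative
hazards.

The implementation is fully vectorized: risk-set sums at every event time are
obtained from prefix sums over rows ordered by interval start and stop, so a
fit on millions of expanded intervals costs a few sorted passes per Newton
iteration.  Strata are folded into a single pass by translating each stratum
onto a disjoint segment of the time axis (risk sets never cross stratum
boundaries, so the translation is exact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CoxFit", "fit_cox", "breslow_cumhaz"]


class CoxFitError(RuntimeError):
    """Raised when a partial-likelihood fit is impossible (e.g. no events)."""


@dataclass
class StratumBaseline:
    """Breslow baseline increments for one stratum."""

    times: np.ndarray  # unique event times, increasing
    increments: np.ndarray  # dLambda0 at those times

    def cumhaz(self, t: np.ndarray) -> np.ndarray:
        """Cumulative baseline hazard Lambda0(t), right-continuous step."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        cum = np.concatenate([[0.0], np.cumsum(self.increments)])
        return cum[idx]


@dataclass
class CoxFit:
    """Result of a weighted counting-process Cox fit."""

    beta: np.ndarray
    cov: np.ndarray
    names: list[str]
    baseline: dict[object, StratumBaseline]
    loglik: float
    n_events: int
    n_rows: int
    converged: bool
    robust_cov: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def robust_se(self) -> np.ndarray:
        c = self.robust_cov if self.robust_cov is not None else self.cov
        return np.sqrt(np.diag(c))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return X @ self.beta

    def cumulative_hazard(self, t, X, stratum=None) -> np.ndarray:
        """Lambda0(t) * exp(x'beta) for each (t, x) pair."""
        base = self.baseline[stratum]
        return base.cumhaz(np.asarray(t, float)) * np.exp(self.linear_predictor(X))


def _risk_sums(values, starts_sorted, stops_sorted, order_start, order_stop, te):
    """Sum of ``values`` over rows at risk (start < te <= stop) at each te.

    ``values`` has shape (n, m); returns (len(te), m).
    """
    pref_start = np.concatenate(
        [np.zeros((1, values.shape[1])), np.cumsum(values[order_start], axis=0)]
    )
    pref_stop = np.concatenate(
        [np.zeros((1, values.shape[1])), np.cumsum(values[order_stop], axis=0)]
    )
    ia = np.searchsorted(starts_sorted, te, side="left")  # starts < te
    ib = np.searchsorted(stops_sorted, te, side="left")  # stops < te (gone)
    return pref_start[ia] - pref_stop[ib]


def fit_cox(
    start,
    stop,
    event,
    X,
    weights=None,
    strata=None,
    cluster=None,
    names=None,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Fit a weighted Cox model on counting-process data.

    Parameters
    ----------
    start, stop : array (n,)
        Interval endpoints; a row is at risk on ``(start, stop]``.
    event : array (n,) of {0, 1}
        Event indicator at ``stop``.
    X : array (n, p)
        Covariates, constant within each interval.
    weights : array (n,), optional
        Case weights (> 0).  Weights may vary across intervals of the same
        subject (time-varying inverse-probability weights).
    strata : array (n,), optional
        Stratum labels; each stratum gets its own baseline hazard while the
        coefficient vector is shared.
    cluster : array (n,), optional
        Cluster labels (e.g. patient ids) for the sandwich covariance.
    """
    start = np.asarray(start, dtype=float)
    stop = np.asarray(stop, dtype=float)
    event = np.asarray(event).astype(bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != start.shape[0]:
        X = X.T
    n, p = X.shape
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("case weights must be strictly positive")
    if np.any(stop <= start):
        raise ValueError("intervals must satisfy start < stop")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    flags: list[str] = []
    # Fold strata into one time axis: translate stratum s onto
    # [s*span, (s+1)*span).  Risk sets are within-stratum, so this is exact.
    if strata is not None:
        strata = np.asarray(strata)
        labels, sid = np.unique(strata, return_inverse=True)
        tmin, tmax = start.min(), stop.max()
        span = (tmax - tmin) + 1.0
        shift = sid * span - tmin
        a, b = start + shift, stop + shift
    else:
        labels, sid = np.array([None], dtype=object), np.zeros(n, dtype=int)
        a, b = start, stop

    if not event.any():
        raise CoxFitError("cannot fit: no events in the data")

    order_start = np.argsort(a, kind="stable")
    order_stop = np.argsort(b, kind="stable")
    starts_sorted = a[order_start]
    stops_sorted = b[order_stop]
    te = b[event]  # (shifted) event times, one entry per event row
    we = w[event]
    Xe = X[event]

    # index pairs for the packed upper triangle of x x^T
    iu, ju = np.triu_indices(p)

    def sums_at_events(beta):
        eta = X @ beta
        eeta = w * np.exp(eta)
        vals = np.empty((n, 1 + p + iu.size))
        vals[:, 0] = eeta
        vals[:, 1 : 1 + p] = X * eeta[:, None]
        vals[:, 1 + p :] = X[:, iu] * X[:, ju] * eeta[:, None]
        S = _risk_sums(vals, starts_sorted, stops_sorted, order_start, order_stop, te)
        S0 = S[:, 0]
        S1 = S[:, 1 : 1 + p]
        S2p = S[:, 1 + p :]
        return eta, S0, S1, S2p

    def unpack_s2(S2p):
        S2 = np.empty((S2p.shape[0], p, p))
        S2[:, iu, ju] = S2p
        S2[:, ju, iu] = S2p
        return S2

    beta = np.zeros(p)
    eta, S0, S1, S2p = sums_at_events(beta)
    ll = float(np.sum(we * (eta[event] - np.log(S0))))
    converged = True
    for _ in range(max_iter if p > 0 else 0):
        converged = False
        zbar = S1 / S0[:, None]
        grad = (we[:, None] * (Xe - zbar)).sum(axis=0)
        S2 = unpack_s2(S2p)
        V = S2 / S0[:, None, None] - zbar[:, :, None] * zbar[:, None, :]
        info = np.einsum("e,eij->ij", we, V)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
            flags.append("singular information matrix; least-squares step")
        # step-halving line search
        for _ in range(30):
            beta_new = beta + step
            eta_n, S0_n, S1_n, S2p_n = sums_at_events(beta_new)
            ll_new = float(np.sum(we * (eta_n[event] - np.log(S0_n))))
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        delta = np.max(np.abs(beta_new - beta))
        beta, eta, S0, S1, S2p, ll = beta_new, eta_n, S0_n, S1_n, S2p_n, ll_new
        if np.max(np.abs(grad)) < tol * max(1.0, abs(ll)) or delta < 1e-11:
            converged = True
            break
    if not converged:
        flags.append("Newton iteration did not reach tolerance")

    zbar = S1 / S0[:, None]
    S2 = unpack_s2(S2p)
    V = S2 / S0[:, None, None] - zbar[:, :, None] * zbar[:, None, :]
    info = np.einsum("e,eij->ij", we, V)
    if p > 0:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(info)
            flags.append("singular information matrix; pseudo-inverse covariance")
    else:
        cov = np.zeros((0, 0))

    # Breslow baseline per stratum: dLambda0(t) = sum_events_at_t w / S0(t)
    tu, inv = np.unique(te, return_inverse=True)
    dsum = np.bincount(inv, weights=we, minlength=tu.size)
    S0u = np.zeros(tu.size)
    # S0 is identical for all events sharing a time; take it from any of them
    S0u[inv] = S0
    dLam = dsum / S0u
    ev_sid = sid[event]
    sid_u = np.zeros(tu.size, dtype=int)
    sid_u[inv] = ev_sid
    # map each unique (shifted) event time back to its exact original value
    orig_u = np.zeros(tu.size)
    orig_u[inv] = stop[event]
    baseline: dict[object, StratumBaseline] = {}
    if strata is not None:
        for s_i, lab in enumerate(labels):
            m = sid_u == s_i
            baseline[lab] = StratumBaseline(orig_u[m], dLam[m])
        for lab in labels:
            if baseline[lab].times.size == 0:
                flags.append(f"stratum {lab!r} has no events; flat baseline")
    else:
        baseline[None] = StratumBaseline(orig_u, dLam)

    robust_cov = None
    if cluster is not None and p > 0:
        span_shift = span if strata is not None else 0.0
        U = _score_residuals(
            a, b, event, X, w, eta, tu, dLam, S0, S1, te, sid, p, span_shift
        )
        cl = np.asarray(cluster)
        _, cid = np.unique(cl, return_inverse=True)
        Usum = np.zeros((cid.max() + 1, p))
        np.add.at(Usum, cid, U)
        meat = Usum.T @ Usum
        robust_cov = cov @ meat @ cov

    return CoxFit(
        beta=beta,
        cov=cov,
        names=list(names),
        baseline=baseline,
        loglik=ll,
        n_events=int(event.sum()),
        n_rows=n,
        converged=converged,
        robust_cov=robust_cov,
        flags=flags,
    )


def _score_residuals(
    a, b, event, X, w, eta, tu, dLam, S0_events, S1_events, te, sid, p, span_shift
):
    """Per-row score residuals U_r (for the sandwich covariance).

    U_r = w_r d_r (x_r - zbar(t_r))
        - w_r e^{eta_r} [ x_r (L0(b_r) - L0(a_r)) - (M(b_r) - M(a_r)) ]
    with L0 the Breslow cumulative baseline and M(t) = sum_{te<=t} zbar dL0,
    all on the (stratum-shifted) time axis, accumulated within stratum.
    """
    n = a.shape[0]
    # zbar at unique event times
    zbar_e = S1_events / S0_events[:, None]
    inv = np.searchsorted(tu, te)
    zbar_u = np.zeros((tu.size, p))
    zbar_u[inv] = zbar_e
    # cumulative within stratum: tu is sorted and strata occupy disjoint
    # time segments, so stratum blocks are contiguous in tu.
    ev_sid = np.zeros(tu.size, dtype=int)
    ev_sid[inv] = sid[event]
    cumL = np.cumsum(dLam)
    cumM = np.cumsum(zbar_u * dLam[:, None], axis=0)
    # subtract the running total at each stratum block start
    block_change = np.flatnonzero(np.diff(ev_sid)) + 1
    offL = np.zeros(tu.size)
    offM = np.zeros((tu.size, p))
    for bc in block_change:
        offL[bc:] = cumL[bc - 1]
        offM[bc:] = cumM[bc - 1]
    cumL_w = cumL - offL
    cumM_w = cumM - offM
    cumL0 = np.concatenate([[0.0], cumL_w])
    cumM0 = np.concatenate([np.zeros((1, p)), cumM_w])
    # shifted stratum block s occupies [s*span_shift, (s+1)*span_shift); a
    # lookup that lands before the row's own block must resolve to zero
    floor_idx = np.searchsorted(tu, sid * span_shift, side="left")

    def lookup(t):
        idx = np.searchsorted(tu, t, side="right")
        idx = np.where(idx <= floor_idx, 0, idx)
        return cumL0[idx], cumM0[idx]

    L_b, M_b = lookup(b)
    L_a, M_a = lookup(a)
    U = -w[:, None] * np.exp(eta)[:, None] * (X * (L_b - L_a)[:, None] - (M_b - M_a))
    zbar_rows = np.zeros((n, p))
    zbar_rows[event] = zbar_e
    U += np.where(event[:, None], w[:, None] * (X - zbar_rows), 0.0)
    return U


def breslow_cumhaz(fit: CoxFit, t, stratum=None) -> np.ndarray:
    """Cumulative baseline hazard of a fitted model at times ``t``."""
    return fit.baseline[stratum].cumhaz(np.asarray(t, dtype=float))
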