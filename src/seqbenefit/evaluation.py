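"""Calibration-based performance assessment over replicated simulations.

For every (patient, cross-section, replication) triple, the estimated
never-treated RMST, post-treatment RMST and benefit are compared with their
ground-truth values.  A local-linear (lowess) smooth of truth on estimate
forms the calibration curve; the root-mean-squared distance between that
curve and the diagonal of perfect calibration, averaged over the points,
summarizes the calibration into one number ("RMS bias").  The smoothing
implicitly marginalizes the patient-specific truth over future covariate
trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .config import EvaluationOptions, RunConfig
from . import pipeline
from .simulate import generate_population

__all__ = ["CalibrationReport", "calibration", "run_replications", "calibration_figure"]

log = logging.getLogger("seqbenefit")

ESTIMANDS = ("rmst0", "rmst1", "benefit")


@dataclass
class CalibrationReport:
    """Smoothed calibration of one method for one estimand."""

    method: str
    estimand: str
    estimated: np.ndarray
    true: np.ndarray
    smoothed: np.ndarray  # smooth of true at each (trimmed) estimated value
    trimmed_mask: np.ndarray
    rms_bias: float
    slope: float
    n_points: int
    flags: list[str] = field(default_factory=list)

    def histogram(self, bins: int = 40):
        return np.histogram(self.estimated, bins=bins)


def calibration(
    estimated,
    true,
    options: EvaluationOptions | None = None,
    method: str = "",
    estimand: str = "",
    rng=None,
) -> CalibrationReport:
    """Smoothed calibration curve and RMS bias of estimates against truth.

    The lowess smooth (local linear, default span 0.75) is fitted on at most
    ``max_smooth_points`` points and evaluated at every estimated value;
    points outside the configured central quantile range of the estimates
    are excluded from the RMS summary to guard against smoother boundary
    artifacts.
    """
    options = options or EvaluationOptions()
    est = np.asarray(estimated, float)
    tru = np.asarray(true, float)
    if est.size < 50:
        raise ValueError("need at least 50 points for a calibration curve")
    flags = []
    if np.ptp(est) < 1e-12:
        flags.append("degenerate (constant) estimates; smooth slope undefined")
        smoothed = np.full(est.size, tru.mean())
        mask = np.ones(est.size, bool)
        rms = float(np.sqrt(np.mean((smoothed - est) ** 2)))
        return CalibrationReport(
            method, estimand, est, tru, smoothed, mask, rms, np.nan, est.size, flags
        )

    rng = rng or np.random.default_rng(0)
    if est.size > options.max_smooth_points:
        sub = rng.choice(est.size, options.max_smooth_points, replace=False)
    else:
        sub = slice(None)
    xs, ys = est[sub], tru[sub]
    span = np.ptp(xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = lowess(
            ys,
            xs,
            frac=options.lowess_frac,
            it=0,
            delta=0.003 * span,
            return_sorted=True,
        )
    # evaluate the fitted curve at every point by interpolation
    cx, cy = curve[:, 0], curve[:, 1]
    cx, uniq = np.unique(cx, return_index=True)
    smoothed = np.interp(est, cx, cy[uniq])
    lo, hi = np.quantile(est, options.trim_quantiles)
    mask = (est >= lo) & (est <= hi)
    rms = float(np.sqrt(np.mean((smoothed[mask] - est[mask]) ** 2)))
    slope = float(np.polyfit(est[mask], smoothed[mask], 1)[0])
    return CalibrationReport(
        method, estimand, est, tru, smoothed, mask, rms, slope, est.size, flags
    )


def run_replications(
    cfg: RunConfig,
    n_runs: int | None = None,
    methods=pipeline.METHODS,
    seed: int | None = None,
    collect_points: bool = False,
):
    """Replicate the simulation study and pool calibration points.

    Per run: generate a population, compute ground truth at every eligible
    (patient, coarse cross-section) point, fit the requested methods, and
    predict the three estimands at every point.  Points are pooled across
    runs into one :class:`CalibrationReport` per (method, estimand).
    Failed runs are logged and skipped; more than the configured fraction
    of failures aborts.
    """
    if n_runs is None:
        n_runs = cfg.evaluation.n_runs
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    run_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(n_runs)]
    pooled: dict[tuple[str, str], list[pd.DataFrame]] = {
        (m, e): [] for m in methods for e in ESTIMANDS
    }
    failures = 0
    for r, rs in enumerate(run_seeds):
        try:
            dgm = cfg.dgm.model_copy(update={"seed": rs})
            pop = generate_population(dgm)
            stacks = pipeline.build_stacks(pop, cfg)
            pts = pipeline.evaluation_points(pop, stacks)
            for m in methods:
                fit = pipeline.fit_method(pop, cfg, m, stacks)
                out = pipeline.predict_points(fit, pts)
                for e in ESTIMANDS:
                    pooled[(m, e)].append(
                        out[[f"est_{e}", f"true_{e}"]].rename(
                            columns={f"est_{e}": "est", f"true_{e}": "true"}
                        )
                    )
        except Exception as exc:  # pragma: no cover - defensive
            failures += 1
            log.warning("replication %d failed: %s", r, exc)
            if failures > cfg.evaluation.max_failure_fraction * n_runs:
                raise RuntimeError(
                    f"{failures} of {r + 1} replications failed; aborting"
                ) from exc
    reports = {}
    rng = np.random.default_rng(root.generate_state(1)[0] % (2**31))
    for (m, e), frames in pooled.items():
        if not frames:
            continue
        df = pd.concat(frames, ignore_index=True)
        reports[(m, e)] = calibration(
            df["est"].to_numpy(),
            df["true"].to_numpy(),
            cfg.evaluation,
            method=m,
            estimand=e,
            rng=rng,
        )
    result = {"reports": reports, "n_runs": n_runs, "failures": failures, "seeds": run_seeds}
    if collect_points:
        result["points"] = pooled
    return result


def bias_table(reports: dict) -> pd.DataFrame:
    """RMS bias per (method, estimand) as a tidy frame."""
    recs = [
        {
            "method": m,
            "estimand": e,
            "rms_bias": rep.rms_bias,
            "slope": rep.slope,
            "n_points": rep.n_points,
        }
        for (m, e), rep in reports.items()
    ]
    return pd.DataFrame(recs)


def calibration_figure(reports: dict, path=None, max_points: int = 4000, seed: int = 0):
    """3x3 panel of calibration curves (methods x estimands) with histograms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    methods = sorted({m for m, _ in reports})
    rng = np.random.default_rng(seed)
    fig, axes = plt.subplots(
        len(methods), len(ESTIMANDS), figsize=(11, 3.4 * len(methods)), squeeze=False
    )
    for i, m in enumerate(methods):
        for j, e in enumerate(ESTIMANDS):
            ax = axes[i][j]
            rep = reports.get((m, e))
            if rep is None:
                ax.axis("off")
                continue
            n = rep.estimated.size
            sub = rng.choice(n, min(n, max_points), replace=False)
            ax.plot(rep.estimated[sub], rep.true[sub], ".", ms=1, alpha=0.15, color="gray")
            order = np.argsort(rep.estimated)
            ax.plot(rep.estimated[order], rep.smoothed[order], "-", color="C0", lw=2)
            lims = [
                min(rep.estimated.min(), rep.true.min()),
                max(rep.estimated.max(), rep.true.max()),
            ]
            ax.plot(lims, lims, "--", color="k", lw=1)
            ax.set_title(f"{m} / {e}  bias={rep.rms_bias:.3f}", fontsize=9)
            hist, edges = rep.histogram()
            hx = 0.5 * (edges[:-1] + edges[1:])
            ax2 = ax.twinx()
            ax2.bar(hx, hist, width=np.diff(edges), color="C1", alpha=0.25)
            ax2.set_yticks([])
            if i == len(methods) - 1:
                ax.set_xlabel("estimated (years)")
            if j == 0:
                ax.set_ylabel("smoothed truth (years)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
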