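"""Tabular and configuration I/O.

CSV dialect: UTF-8, header row, '.' decimal, full float precision unless a
rounding switch is used.  Configurations round-trip through YAML or JSON;
fitted models serialize to a small versioned bundle (coefficients as JSON,
baseline step functions as CSV).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import RunConfig
from .coxmodel import CoxFit, StratumBaseline
from .msm import MSMFit
from .simulate import OfferStream, Population

BUNDLE_VERSION = 1

EPISODE_COLUMNS = [
    "patient_id",
    "s_entry",
    "X",
    "delta",
    "treated",
    "censor_admin",
    "T",
    "Zstar",
    "post_time",
    "post_delta",
]


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.model_dump(), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_config(cfg: RunConfig, path) -> None:
    path = Path(path)
    data = cfg.model_dump(mode="json")
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=True))
    else:
        path.write_text(json.dumps(data, indent=2, sort_keys=True))


def read_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return RunConfig.model_validate(data)


def write_table(df: pd.DataFrame, path, round_times: int | None = None) -> None:
    df = df.copy()
    if round_times is not None:
        for c in df.columns:
            if df[c].dtype.kind == "f":
                df[c] = df[c].round(round_times)
    # %.17g guarantees exact float64 round trips through text
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path, required=None) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_population(pop: Population, outdir, measurements: bool = True, round_times: int | None = None) -> None:
    """Write episodes / offers / (optionally) long measurements CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(pop.episodes[EPISODE_COLUMNS], outdir / "episodes.csv", round_times)
    write_table(
        pop.offer_stream.offers[["date_idx", "date", "Zstar", "patient_id"]],
        outdir / "offers.csv",
        round_times,
    )
    if measurements:
        write_table(pop.measurements_long(), outdir / "measurements.csv", round_times)


def read_offer_stream(path, dates_coarse, dates_fine) -> OfferStream:
    offers = read_table(path, required=["date_idx", "date", "Zstar", "patient_id"])
    return OfferStream(
        dates_coarse=np.asarray(dates_coarse, float),
        dates_fine=np.asarray(dates_fine, float),
        offers=offers,
    )


# ---------------------------------------------------------------------------
# fit bundles


def _baseline_frame(fit: CoxFit, arm: str) -> pd.DataFrame:
    recs = []
    for key, bl in fit.baseline.items():
        recs.append(
            pd.DataFrame(
                {
                    "arm": arm,
                    "stratum": "" if key is None else str(key),
                    "time": bl.times,
                    "increment": bl.increments,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def write_fit_bundle(fit: MSMFit, outdir, cfg: RunConfig | None = None) -> None:
    """Serialize an MSM fit: coefficients JSON + baseline CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "bundle_version": BUNDLE_VERSION,
        "method": fit.method,
        "horizon": fit.horizon,
        "covariates0": fit.covariates0,
        "covariates1": fit.covariates1,
        "beta0": fit.fit0.beta.tolist(),
        "beta1": fit.fit1.beta.tolist(),
        "se0": fit.fit0.robust_se.tolist(),
        "se1": fit.fit1.robust_se.tolist(),
        "baseline_mode": fit.options.baseline,
        "roles": fit.roles.model_dump(),
        "options": fit.options.model_dump(),
        "config_hash": config_hash(cfg) if cfg is not None else None,
        "diagnostics": {k: v for k, v in fit.diagnostics.items() if np.isscalar(v)},
    }
    (outdir / "fit.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    bl = pd.concat(
        [_baseline_frame(fit.fit0, "never_treated"), _baseline_frame(fit.fit1, "treated_at_k")],
        ignore_index=True,
    )
    write_table(bl, outdir / "baselines.csv")


def read_fit_bundle(outdir) -> MSMFit:
    from .config import CovariateRoles, MSMOptions

    outdir = Path(outdir)
    meta = json.loads((outdir / "fit.json").read_text())
    if meta["bundle_version"] != BUNDLE_VERSION:
        raise ValueError(f"unsupported bundle version {meta['bundle_version']}")
    bl = read_table(outdir / "baselines.csv")

    def build(arm, beta, names):
        baseline = {}
        for s, grp in bl[bl["arm"] == arm].groupby("stratum", dropna=False):
            key = None if (s == "" or pd.isna(s)) else _parse_stratum(s)
            baseline[key] = StratumBaseline(
                grp["time"].to_numpy(), grp["increment"].to_numpy()
            )
        if not baseline:
            baseline[None] = StratumBaseline(np.array([]), np.array([]))
        return CoxFit(
            beta=np.asarray(beta, float),
            cov=np.full((len(beta), len(beta)), np.nan),
            names=names,
            baseline=baseline,
            loglik=np.nan,
            n_events=-1,
            n_rows=-1,
            converged=True,
        )

    fit = MSMFit(
        fit0=build("never_treated", meta["beta0"], meta["covariates0"]),
        fit1=build("treated_at_k", meta["beta1"], meta["covariates1"]),
        covariates0=meta["covariates0"],
        covariates1=meta["covariates1"],
        horizon=meta["horizon"],
        options=MSMOptions.model_validate(meta["options"]),
        roles=CovariateRoles.model_validate(meta["roles"]),
        method=meta["method"],
    )
    return fit


def _parse_stratum(s: str):
    try:
        f = float(s)
        return int(f) if f == int(f) else f
    except ValueError:
        return s
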