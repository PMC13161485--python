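import numpy as np
import pandas as pd
import pytest

from seqbenefit.config import DGMConfig, RunConfig
from seqbenefit.pipeline import build_stacks
from seqbenefit.simulate import generate_population


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig(dgm=DGMConfig(n_patients=500, seed=11), seed=11)


@pytest.fixture(scope="session")
def pop500(default_cfg):
    return generate_population(default_cfg.dgm)


@pytest.fixture(scope="session")
def stacks500(pop500, default_cfg):
    return build_stacks(pop500, default_cfg)


# the 4-subject toy: (z, time, event) with two events; the brute-force
# partial-likelihood maximizer is beta = -0.5*ln 2
TOY_Z = np.array([1.0, 0.0, 1.0, 0.0])
TOY_T = np.array([2.0, 1.0, 3.0, 3.0])
TOY_D = np.array([1, 1, 0, 0])
TOY_BETA = -0.5 * np.log(2.0)


def brute_force_cox_1d(z, t, d, grid=None):
    """Independent oracle: grid/golden-section maximization of the
    Breslow partial likelihood for a single covariate."""
    from scipy.optimize import minimize_scalar

    z, t, d = map(np.asarray, (z, t, d))

    def negll(b):
        ll = 0.0
        for i in np.flatnonzero(d):
            risk = t >= t[i]
            ll += b * z[i] - np.log(np.sum(np.exp(b * z[risk])))
        return -ll

    res = minimize_scalar(negll, bounds=(-8, 8), method="bounded", options={"xatol": 1e-10})
    return float(res.x)


@pytest.fixture(scope="session")
def toy_oracle_beta():
    return brute_force_cox_1d(TOY_Z, TOY_T, TOY_D)


def toy_episodes(as_treatment=True):
    """The toy rendered as an episode table (events = treatment or death)."""
    return pd.DataFrame(
        {
            "patient_id": np.arange(4),
            "s_entry": 0.0,
            "X": TOY_T,
            "delta": TOY_D if not as_treatment else 0,
            "treated": TOY_D if as_treatment else 0,
            "censor_admin": 1 - TOY_D,
            "T": np.where(TOY_D == 1, TOY_T, np.nan) if as_treatment else np.nan,
            "Zstar": np.nan,
            "post_time": np.nan,
            "post_delta": 0,
        }
    )


def toy_measurements():
    return pd.DataFrame({"patient_id": np.arange(4), "t": 0.0, "Z": TOY_Z})
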