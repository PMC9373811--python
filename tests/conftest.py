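import numpy as np
import pandas as pd
import pytest

from tiiclnc import screen as screen_mod
from tiiclnc import synthdata
from tiiclnc.exprprep import ExpressionMatrix
from tiiclnc.survlearn import SurvivalData


def make_survival(n, beta, seed, censor_scale=None, p=None):
    """Exponential PH data with known coefficients (test helper)."""
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = p or len(beta)
    X = rng.normal(size=(n, p))
    lp = X[:, : len(beta)] @ beta
    t = rng.exponential(1.0 / (0.1 * np.exp(lp)))
    if censor_scale is None:
        time, event = t, np.ones(n, dtype=int)
    else:
        c = rng.exponential(censor_scale, size=n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
    return SurvivalData(np.maximum(time, 1e-9), event, X)


@pytest.fixture(scope="session")
def small_config():
    """Scaled-down study for cheap integration tests."""
    return synthdata.SimulationConfig(
        n_lnc=400, lines_per_type=3, n_patients=150, n_cohorts=2,
        frac_general=0.04, n_prognostic=6, seed=9,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return synthdata.generate_study(small_config)


@pytest.fixture(scope="session")
def default_study():
    """The full default study conditions (fixed seed), generated once."""
    cfg = synthdata.SimulationConfig(seed=11)
    return cfg, synthdata.generate_study(cfg)


@pytest.fixture(scope="session")
def default_trace(default_study):
    _, (immune, ann, tumor, cohorts, gt) = default_study
    return screen_mod.run_screen(immune, ann, tumor, cohorts[0])


def linear_matrix(values, features=None, samples=None, scale="linear_tpm"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    features = features or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=features, columns=samples), scale)
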