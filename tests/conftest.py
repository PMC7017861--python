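import numpy as np
import pytest

import wetstate as ws
from wetstate.simulate import SyntheticConfig, study_like_config, simulate_study

INTERIOR_BETA = {
    "init:logit_psi": 0.8, "init:logit_R": -0.3,
    "psi:int[m0]": -0.8, "psi:int[m1]": 1.2, "psi:int[m2]": 1.8,
    "R:int[m0]": -1.0, "R:int[m1]": -1.5, "R:int[m2]": 1.5,
    "delta:int": 1.2,
}


def interior_config(n_sites=800, n_years=10, **kw):
    """Constant-parameter truth at interior probabilities (no covariates)."""
    return SyntheticConfig(n_sites=n_sites, n_years=n_years,
                           structure="psi[m](.) R[m](.) delta(.)",
                           beta=dict(INTERIOR_BETA), **kw)


@pytest.fixture(scope="session")
def small_truth():
    """Small study-like synthetic dataset with known truth."""
    return simulate_study(study_like_config(n_sites=60, n_years=6), seed=7)


@pytest.fixture(scope="session")
def interior_truth():
    return simulate_study(interior_config(), seed=9)


@pytest.fixture(scope="session")
def interior_fit(interior_truth):
    return ws.fit_model(interior_truth.config.structure, interior_truth.data,
                        n_starts=1, seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240817)
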