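import numpy as np
import pytest

import ebatest as e


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def one_factor_pop():
    """One-factor p=5 population: loadings drawn once, unit variances."""
    r = np.random.default_rng(77)
    lam = r.uniform(0.5, 1.5, 5)
    sigma = np.outer(lam, lam) + np.eye(5)
    return lam, sigma


@pytest.fixture(scope="session")
def study1_pop():
    return e.build_study_population("study1", 15, seed=3)


@pytest.fixture(scope="session")
def invariance_pop():
    return e.build_study_population("study2", 5, G=2, seed=3)
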