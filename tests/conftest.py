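import numpy as np
import pytest

from phytodoe import (GeneratorConfig, RSMFit, fit_rsm, full_factorial,
                      replicate_design, simulate_uptake)
from phytodoe import reference as R


@pytest.fixture(scope="session")
def factors():
    return list(R.FACTORS)


@pytest.fixture(scope="session")
def study_design(factors):
    """The reference 3x3x3 design replicated 3x (81 rows, 27 runs)."""
    return replicate_design(full_factorial(factors), 3)


@pytest.fixture(scope="session")
def study_uptake(study_design):
    """One simulated replicate dataset at the default noise levels."""
    return simulate_uptake(study_design, GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def cd_fit(study_design, study_uptake):
    return fit_rsm(study_design, study_uptake["Cd"].to_numpy(), response="Cd")


@pytest.fixture(scope="session")
def published_fits():
    """Fits reconstructed from the published coefficient columns and stars."""
    return {
        m: RSMFit.from_published(m, R.FACTOR_NAMES, R.COEFFICIENTS[m], R.STARS[m])
        for m in R.RESPONSE_METALS
    }


def ols_oracle(X, y):
    """Brute-force normal-equation solution, independent of the fit path."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return np.linalg.solve(X.T @ X, X.T @ y)
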