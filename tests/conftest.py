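import numpy as np
import pytest

import astrobiodose as abd
from astrobiodose.simulate import SimConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort (43 crew-missions) with truth."""
    return abd.simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pre_fit_full(default_cohort):
    cohort, _ = default_cohort
    return abd.fit_preflight(cohort, include_baseline=True)


@pytest.fixture(scope="session")
def pre_fit_nb(default_cohort):
    cohort, _ = default_cohort
    return abd.fit_preflight(cohort, include_baseline=False)


@pytest.fixture(scope="session")
def post_fit(default_cohort, pre_fit_nb):
    cohort, _ = default_cohort
    design = abd.assemble_postflight_design(cohort, pre_fit_nb)
    return abd.fit_postflight(design)


@pytest.fixture(scope="session")
def tiny_intercept_model():
    """2 subjects x 3 rows, random intercept only: small enough for dense-grid
    and Monte-Carlo integration oracles."""
    from astrobiodose import glmm

    X = np.column_stack([np.ones(6), np.repeat([0.0, 0.2, 0.4], 2)])
    groups = np.array([0, 1, 0, 1, 0, 1])
    off = np.log(np.array([2000.0, 1500, 1500, 1500, 1500, 1500]))
    spec = glmm.ModelSpec(
        X, ["const", "dose"], np.ones((6, 1)), ["const"], groups, ["a", "b"], off
    )
    k = np.array([6.0, 5, 14, 11, 33, 25])
    beta = np.array([-5.5, 4.0])
    sigma0 = 0.5
    return spec, k, beta, sigma0
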