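import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import prevmap as pm

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_grid():
    return pm.GridDefinition(n_rows=20, n_cols=20, cell_size=1.0)


@pytest.fixture(scope="session")
def toy_data(small_grid):
    """A small synthetic study region with one informative covariate."""
    stack = pm.generate_covariate_surfaces(small_grid, 1, seed=31)
    truth = pm.make_truth(small_grid, stack, [-2.5, 0.8], 1.0, 6.0, nu=1.0, seed=32)
    survey = pm.simulate_survey(truth, 50, 20, seed=33)
    design = pm.build_design(survey, stack)
    return dict(stack=stack, truth=truth, survey=survey, design=design)


@pytest.fixture(scope="session")
def toy_model(toy_data):
    """A fitted spatial model on the toy region (shared; do not mutate)."""
    spec = pm.ModelSpec(n_posterior_samples=300, n_warmup=300, seed=7)
    return pm.fit(toy_data["design"], spec)


@pytest.fixture(scope="session")
def toy_prediction(toy_model, toy_data):
    return pm.predict_grid(toy_model, toy_data["stack"], n_samples=200, seed=5)
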