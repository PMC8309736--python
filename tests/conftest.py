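import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gaitspm.synth import TemplateSet, default_study_model, generate_trial

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("gaitspm").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def study_model_effects():
    return default_study_model()


@pytest.fixture(scope="session")
def study_model(study_model_effects):
    return study_model_effects[0]


@pytest.fixture(scope="session")
def study_effects(study_model_effects):
    return study_model_effects[1]


@pytest.fixture(scope="session")
def templates(study_model):
    return TemplateSet(study_model)


@pytest.fixture(scope="session")
def noiseless_trial(study_model, templates):
    """Grid-aligned, noise-free WR trial with ground truth."""
    model = study_model.noiseless().grid_aligned()
    rec, truth = generate_trial(model, "WR", subject_seed=1, trial_seed=2, templates=TemplateSet(model))
    return model, rec, truth


@pytest.fixture(scope="session")
def noisy_trial(study_model, templates):
    """Default-noise WR trial with ground truth."""
    rec, truth = generate_trial(study_model, "WR", subject_seed=3, trial_seed=4, templates=templates)
    return study_model, rec, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
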