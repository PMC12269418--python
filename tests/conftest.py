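import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def run_config():
    from mvnquant.pipeline import RunConfig

    return RunConfig(seed=7)


@pytest.fixture(scope="session")
def trained_classifier(run_config):
    """One vessel classifier trained on synthetic scenes, shared by the
    segmentation-quality and pipeline tests."""
    from mvnquant.pipeline import train_classifier_on_scenes
    from mvnquant.synthetic import generate_condition_batch

    scenes, _ = generate_condition_batch(4, 2.0, seed=123)
    return train_classifier_on_scenes(scenes, run_config)
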