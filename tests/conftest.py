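import numpy as np
import pytest

from fenceline import PipelineConfig, SimConfig, run_training
from fenceline.simulate import simulate_campaign


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def small_campaign(sim_config):
    """One seeded training campaign: 12 presentations per class."""
    return simulate_campaign(
        sim_config, samples_per_class=12, campaign_id="T", role="train", seed=101
    )


@pytest.fixture(scope="session")
def test_campaign(sim_config):
    """A held-out campaign four months later, 8 presentations per class."""
    return simulate_campaign(
        sim_config,
        samples_per_class=8,
        campaign_id="F",
        role="test",
        seed=202,
        age_months=4.0,
    )


@pytest.fixture(scope="session")
def pipeline_config():
    # small-campaign settings: fewer folds, no selection step
    return PipelineConfig(cv=5, select_features=False, seed=11)


@pytest.fixture(scope="session")
def trained_bundle(small_campaign, pipeline_config):
    return run_training(small_campaign, pipeline_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
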