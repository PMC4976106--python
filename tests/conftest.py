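import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mesocon import PhotoParams
from mesocon.pipeline import PipelineOptions, run_pipeline
from mesocon.simulate import DroughtCampaignConfig, simulate_campaign

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture
def params():
    """Healthy-leaf parameter set with round numbers for hand arithmetic."""
    return PhotoParams(gamma_star=35.0, Rd=2.0, Vcmax=100.0, alpha_beta=0.425)


@pytest.fixture(scope="session")
def noiseless_campaign():
    return simulate_campaign(DroughtCampaignConfig(seed=1).noiseless())


@pytest.fixture(scope="session")
def noiseless_result(noiseless_campaign):
    """Full pipeline on the noiseless campaign, fit on the chloroplast-CO2
    basis to match the generating demand."""
    return run_pipeline(
        noiseless_campaign.records,
        PipelineOptions(vcmax_basis="cc", vcmax_use_rd=False),
        truth=noiseless_campaign.truth)


@pytest.fixture(scope="session")
def noisy_campaign():
    return simulate_campaign(DroughtCampaignConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
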