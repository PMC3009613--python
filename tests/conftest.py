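import pytest

from lbpcea.config import default_config
from lbpcea.pipeline import base_case
from lbpcea.psa import run_psa


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def base(config):
    """Deterministic base-case run of both strategies."""
    return base_case(config)


@pytest.fixture(scope="session")
def psa_samples(config):
    """A moderately sized PSA run shared across tests (2,000 draws)."""
    settings = config.model_settings()
    return run_psa(
        config.distribution_specs(),
        config.mortality_schedule(),
        settings,
        config.engine_conventions(),
        n_draws=2_000,
        seed=7,
    )


@pytest.fixture(scope="session")
def degenerate_samples(config):
    """PSA collapsed to the point values (all distributions fixed)."""
    settings = config.model_settings()
    return run_psa(
        config.fixed_specs(),
        config.mortality_schedule(),
        settings,
        config.engine_conventions(),
        n_draws=20,
        seed=3,
    )
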