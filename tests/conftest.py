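import numpy as np
import pytest
from hypothesis import settings

from ppibayes import UniverseConfig, generate_universe
from ppibayes.pipeline import run_pipeline

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> UniverseConfig:
    """A small but non-degenerate universe used across modules."""
    return UniverseConfig(
        n_proteins=80,
        true_density=0.06,
        rho_signal=0.7,
        ddi_signal=0.7,
        interolog_fidelity=0.7,
        source_noise=0.2,
        n_samples=30,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    return generate_universe(small_config)


@pytest.fixture(scope="session")
def small_result(small_config, small_universe):
    """Full pipeline (network + hubs) on the small universe."""
    return run_pipeline(
        small_config,
        universe=small_universe,
        lr_cutoff=5.0,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
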