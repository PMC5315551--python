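import numpy as np
import pytest

from sstdbs import (
    RaceParams,
    TaskConfig,
    default_templates,
    simulate_session,
    synthesize_eeg,
)


@pytest.fixture(scope="session")
def default_config() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def default_params() -> RaceParams:
    return RaceParams()


@pytest.fixture(scope="session")
def small_session(default_params):
    cfg = TaskConfig(n_blocks=1, trials_per_block=100)
    return simulate_session(cfg, default_params, seed=5)


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def low_noise_eeg(small_session, templates):
    return synthesize_eeg(small_session, templates, noise_sd=0.1, seed=7)
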