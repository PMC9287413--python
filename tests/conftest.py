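import numpy as np
import pytest

from ctblab import DesignConfig, StudyConfig, TreatmentEffect, build_mcg_design
from ctblab.simulate import reduced_study_config


@pytest.fixture(scope="session")
def default_design_config() -> DesignConfig:
    return DesignConfig()


@pytest.fixture(scope="session")
def default_mcg_design(default_design_config):
    return build_mcg_design(default_design_config, seed=123)


@pytest.fixture(scope="session")
def tiny_study_config() -> StudyConfig:
    """2+2 participants, 60 MCG / 20 MGT trials per session: fast end-to-end."""
    return reduced_study_config(n_per_group=2, n_mgt_trials=20)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
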