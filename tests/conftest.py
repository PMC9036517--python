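import dataclasses

import numpy as np
import pytest

from curvsense import GeneratorConfig, generate_membrane_frames

#: Default sigmoid parameters of the study geometry: plateaus 15/11 nm,
#: transition at 8.5 nm.
DEFAULT_PARAMS = (15.0, 0.527, 11.0, 1.0, 8.5)


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    cfg = GeneratorConfig(n_frames=3, seed=11)
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def membrane_frames(gen_config):
    return generate_membrane_frames(gen_config)


@pytest.fixture(scope="session")
def pc_only_config(gen_config) -> GeneratorConfig:
    return dataclasses.replace(gen_config, pip2_fraction=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
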