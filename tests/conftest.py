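import numpy as np
import pytest

from capen import EffectSpec, PipelineConfig, Recording, simulate_trial
from capen.pipeline import connectivity_table
from capen.presets import reduced_config, reduced_design


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def tiny_design():
    return reduced_design(n_per_arm=4)


@pytest.fixture(scope="session")
def pipe_config():
    return reduced_config()


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design):
    """A small but complete simulated trial (4/arm, reduced scale)."""
    return simulate_trial(tiny_design, EffectSpec(), seed=7)


@pytest.fixture(scope="session")
def tiny_table(tiny_dataset, tiny_design, pipe_config):
    def get(sid, tp, cond):
        return Recording(
            tiny_dataset.recordings[(sid, tp, cond)],
            tiny_design.rate,
            list(tiny_dataset.channels),
        )

    return connectivity_table(get, tiny_dataset.subjects, pipe_config)
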