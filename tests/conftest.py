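import numpy as np
import pytest

import propgest as pg
from propgest.synthetic import SimulatorConfig


@pytest.fixture(scope="session")
def sim_config() -> SimulatorConfig:
    return SimulatorConfig()


@pytest.fixture(scope="session")
def small_corpus():
    """3 simulated subjects x 2 trials: enough to train, fast to build."""
    return pg.make_corpus(seed=7, n_subjects=3, n_trials=2)


@pytest.fixture(scope="session")
def one_trial(sim_config):
    plan = pg.make_choreography(1, config=sim_config)
    return pg.synthesize_trial(plan, sim_config)


@pytest.fixture(scope="session")
def noiseless_trial():
    cfg = SimulatorConfig(noise_sd=0.0)
    plan = pg.make_choreography(5, config=cfg)
    return pg.synthesize_trial(plan, cfg), cfg


@pytest.fixture(scope="session")
def windows30(one_trial):
    return pg.slide(one_trial, pg.WindowParams(30, 5))
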