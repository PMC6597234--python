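import numpy as np
import pytest

from dipsim import act_baseline
from dipsim.physiology import PhysiologyParams
from dipsim.population_chain import generate_population_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def params():
    return PhysiologyParams()


@pytest.fixture
def pop_table():
    return generate_population_table(10_000, 0.2, seed=1)


@pytest.fixture(scope="session")
def small_config():
    """A fast scenario: 3,000 women, short burn-in, story recording off."""
    cfg = act_baseline(n_women=3000, seed=1)
    cfg.record_stories = False
    return cfg


@pytest.fixture(scope="session")
def small_result(small_config):
    from dipsim import run
    return run(small_config, seed=7)
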