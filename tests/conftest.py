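import numpy as np
import pytest
from hypothesis import settings

from spikepatterns import ClassifierConfig, SpikeTrain

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def cfg():
    return ClassifierConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20180627)


def make_train(times, t_start=0.0, t_stop=None, unit_id="u0"):
    return SpikeTrain(unit_id, np.asarray(times, dtype=float),
                      t_start=t_start, t_stop=t_stop)


@pytest.fixture
def mk_train():
    return make_train
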