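import numpy as np
import pytest

from ktcc import design as dg
from ktcc import stimuli as st


@pytest.fixture(scope="session")
def full_ensemble():
    return st.build_full_ensemble(seed=11)


@pytest.fixture(scope="session")
def subsample(full_ensemble):
    return st.subsample_balanced(full_ensemble, 56, seed=12)


@pytest.fixture(scope="session")
def schedule(subsample):
    return st.schedule_session(subsample, seed=13)


@pytest.fixture(scope="session")
def timeline(schedule, subsample):
    return dg.timeline_from_schedule(schedule, stimuli=subsample)


@pytest.fixture(scope="session")
def fir_design(timeline):
    return dg.build_fir_design(timeline)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
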