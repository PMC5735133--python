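import numpy as np
import pytest

from priorclarity import design, simulate


@pytest.fixture(scope="session")
def word_pool():
    return simulate.default_word_pool(400)


@pytest.fixture(scope="session")
def response_sets():
    return design.default_response_sets()


@pytest.fixture(scope="session")
def exp1_schedule(word_pool):
    return design.build_exp1_schedule(word_pool, "A", seed=11)


@pytest.fixture(scope="session")
def exp2_trials(response_sets):
    return design.build_exp2_schedule(response_sets, seed=11)


@pytest.fixture(scope="session")
def s_table():
    # plausible per-channel sensory precisions for a mid-ability listener
    return {4: 0.4, 8: 0.6, 16: 0.85}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
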