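import numpy as np
import pytest

from transdx.bandit_env import generate_schedule, label_correct
from transdx.rl_models import RLParams, simulate_agent
from transdx.synthetic_cohort import cohort_summaries, generate_cohort, get_scenario


@pytest.fixture(scope="session")
def schedule():
    """Default-parameter drifting schedule, 500 trials."""
    return generate_schedule(seed=1)


@pytest.fixture(scope="session")
def labeling(schedule):
    return label_correct(schedule)


@pytest.fixture(scope="session")
def rl2b_params():
    return RLParams(alpha=0.35, beta=4.0, gamma=-0.6, alpha_F=0.1, alpha_C=0.5)


@pytest.fixture(scope="session")
def rl2b_session(schedule, rl2b_params):
    return simulate_agent(schedule, "reward", "RL2b", rl2b_params, seed=5)


@pytest.fixture(scope="session")
def smoke_cohort():
    return generate_cohort(get_scenario("small_n_smoke"), seed=3)


@pytest.fixture(scope="session")
def paper_like_cohort():
    return generate_cohort(get_scenario("paper_like"), seed=100)


@pytest.fixture(scope="session")
def paper_like_summaries(paper_like_cohort):
    return cohort_summaries(paper_like_cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
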