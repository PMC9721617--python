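import numpy as np
import pandas as pd
import pytest

from twostep import M1Params, default_config, generate_session_walks, simulate_choices
from twostep.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return default_config(n_trials=60, seed=11)


@pytest.fixture(scope="session")
def small_walks(small_config):
    return generate_session_walks(small_config, seed=5)


@pytest.fixture(scope="session")
def m1_session(small_config, small_walks):
    params = M1Params(omega=0.6, gamma=0.3, eta=2.0)
    return simulate_choices(params, "M1", small_config, small_walks, seed=9)


@pytest.fixture(scope="session")
def tiny_cohort():
    """12 subjects x 2 sessions x 80 trials, all three arms, M1 generator."""
    spec = CohortSpec(
        n_per_arm={"placebo": 4, "amisulpride": 4, "naltrexone": 4},
        n_trials=80, master_seed=101,
    )
    trials, truth = generate_cohort(spec)
    return spec, trials, truth
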