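import numpy as np
import pandas as pd
import pytest

from effortddm.hierarchical_fit import FitConfig
from effortddm.synthetic_cohort import CohortSpec, TaskDesign, simulate_cohort


@pytest.fixture(scope="session")
def default_design():
    return TaskDesign()


@pytest.fixture(scope="session")
def small_cohort():
    """8 synthetic participants with default generating structure."""
    trials, covs = simulate_cohort(CohortSpec(n_participants=8, seed=101))
    return trials, covs


@pytest.fixture(scope="session")
def tiny_fit_config():
    return FitConfig(n_chains=2, n_samples=500, n_burn_in=200, seed=7)


def make_trials(rts, pid="p001", choice="accept"):
    """Minimal trial table around a list of reaction times."""
    n = len(rts)
    return pd.DataFrame({
        "participant_id": pid,
        "block": 1,
        "trial_index": np.arange(1, n + 1),
        "reward": 6,
        "effort": 0.38,
        "choice": choice,
        "rt": np.asarray(rts, float),
        "exempt": False,
    })
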