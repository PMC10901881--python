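import numpy as np
import pandas as pd
import pytest

from tacstrial import cohort, preprocess
from tacstrial.sequence import PatternSequence, generate_session


@pytest.fixture(scope="session")
def pattern3241() -> PatternSequence:
    return PatternSequence((3, 2, 4, 1))


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study, shared across tests (seeded)."""
    model = cohort.GenerativeModel()
    profiles = cohort.sample_cohort(model=model, rng_seed=11)
    trials = cohort.simulate_responses(profiles, model, rng_seed=22)
    return model, profiles, trials


@pytest.fixture(scope="session")
def default_aggregates(default_study):
    _, _, trials = default_study
    filtered, report = preprocess.filter_trials(trials)
    agg = preprocess.aggregate_epochs(filtered)
    return agg, report


@pytest.fixture(scope="session")
def noisefree_study():
    """Deterministic study: no random effects, no noise, perfect accuracy
    is not possible (accuracy stays stochastic) but RTs are exact."""
    model = cohort.GenerativeModel(
        sd_intercept=0.0,
        sd_epoch_slope=0.0,
        cell_sd=0.0,
        trial_lognorm_sigma=0.0,
    )
    profiles = cohort.sample_cohort(model=model, rng_seed=5)
    trials = cohort.simulate_responses(profiles, model, rng_seed=6)
    return model, profiles, trials


@pytest.fixture(scope="session")
def single_session(pattern3241) -> pd.DataFrame:
    return generate_session(pattern3241, rng_seed=42)
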