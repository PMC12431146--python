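import numpy as np
import pandas as pd
import pytest

from glucolens.behavior_features import FEATURE_SETS, assemble_features
from glucolens.experiments import SplitPlan, make_split
from glucolens.predictors import train_soft_voting_classifier
from glucolens.synthetic_cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def bundle():
    """Default-condition cohort: 10 participants, 6 workdays x 3 phases.

    Six workdays per phase leaves 150 complete rows under the 'All' set
    after each phase's first day (which has no prior same-phase work log
    for the self-report score) is dropped.
    """
    return generate_cohort(CohortConfig(seed=7, workdays_per_phase=6))


@pytest.fixture(scope="session")
def features_all(bundle):
    return assemble_features(
        bundle.cgm, bundle.activity, bundle.meals, bundle.work,
        bundle.bmi_by_participant(), "All",
    )


@pytest.fixture(scope="session")
def feature_names():
    return FEATURE_SETS["All"]


@pytest.fixture(scope="session")
def split(features_all):
    return make_split(features_all, SplitPlan(scheme="ratio", seed=0))


@pytest.fixture(scope="session")
def ensemble(split, feature_names):
    train, _ = split
    return train_soft_voting_classifier(train, feature_names, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_trace(rng, n=13, start="2022-03-07 12:00", step_min=15):
    """A random CGM window fixture as (timestamps, glucose)."""
    ts = pd.date_range(start, periods=n, freq=f"{step_min}min")
    glucose = rng.uniform(70, 180, size=n)
    return list(ts), list(glucose)
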