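import numpy as np
import pytest
from hypothesis import settings

from eegworkload.features import EpochingConfig, extract_features
from eegworkload.synth import (HIGH, LOW, TRANSITION, SignalModelParams,
                               StudySchedule, generate_session)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


#: compact session: 32 epochs per class, enough for the 20+11 epoch protocols
SHORT_PLAN = (
    (TRANSITION, 60.0), (HIGH, 185.0), (TRANSITION, 60.0),
    (LOW, 185.0), (TRANSITION, 60.0),
)

#: 300 s per workload state -> 55 epochs per class, the full-session layout
FEATURE_PLAN = (
    (TRANSITION, 60.0), (HIGH, 300.0), (TRANSITION, 60.0),
    (LOW, 300.0), (TRANSITION, 60.0),
)


@pytest.fixture(scope="session")
def short_schedule():
    return StudySchedule(n_subjects=1, days=1, sessions_per_day=1,
                         session_length_s=550.0, block_plan=SHORT_PLAN)


@pytest.fixture(scope="session")
def feature_schedule():
    return StudySchedule(n_subjects=1, days=1, sessions_per_day=1,
                         session_length_s=780.0, block_plan=FEATURE_PLAN)


@pytest.fixture(scope="session")
def strong_session(short_schedule):
    """One session with the default (strongly separable) workload signature."""
    return generate_session(SignalModelParams(), short_schedule, seed=42)


@pytest.fixture(scope="session")
def strong_features(strong_session):
    rec, labels = strong_session
    return extract_features(rec, labels, EpochingConfig())


@pytest.fixture(scope="session")
def cluster_features():
    """Linearly separable two-cluster feature set (10 sd separation)."""
    from eegworkload.features import FeatureSet

    rng = np.random.default_rng(0)
    n = 40
    X = np.vstack([rng.normal(0.0, 1.0, (n, 147)),
                   rng.normal(10.0, 1.0, (n, 147))])
    labels = np.array([HIGH] * n + [LOW] * n, dtype=object)
    return FeatureSet(X, np.arange(2 * n) * 5.0, labels,
                      tuple(f"f{i}" for i in range(147)))
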