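import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_ds():
    from neuroasym import fixture_cohort

    return fixture_cohort()


@pytest.fixture(scope="session")
def fixture_df(fixture_ds):
    return fixture_ds.to_frame()


@pytest.fixture(scope="session")
def fitted(fixture_ds):
    from neuroasym import BlinkMRIDiagnosis

    return BlinkMRIDiagnosis.from_cohort(fixture_ds).fit()


def pair_counting_auc(pos, neg):
    """Mann-Whitney pair-counting AUC oracle: concordant + half-ties."""
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))
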