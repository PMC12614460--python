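import numpy as np
import pandas as pd
import pytest

from salp_clinrisk import cohort


@pytest.fixture(scope="session")
def table1_specs():
    return cohort.default_table1_specs()


@pytest.fixture(scope="session")
def default_cohort(table1_specs):
    """One full-size complete synthetic cohort, shared across tests."""
    return cohort.generate_cohort(table1_specs, cohort.GeneratorConfig(seed=1234))


@pytest.fixture(scope="session")
def missing_cohort(table1_specs, default_cohort):
    return cohort.inject_missingness(default_cohort, table1_specs, seed=99)


def make_blobs_frame(n=200, n_features=4, separation=6.0, event_frac=0.2, seed=0):
    """Two well-separated Gaussian blobs as a labelled cohort table."""
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * event_frac))
    X_neg = rng.standard_normal((n - n_pos, n_features))
    X_pos = rng.standard_normal((n_pos, n_features)) + separation
    X = np.vstack([X_neg, X_pos])
    y = np.concatenate([np.zeros(n - n_pos, int), np.ones(n_pos, int)])
    order = rng.permutation(n)
    df = pd.DataFrame(X[order], columns=[f"f{i}" for i in range(n_features)])
    df[cohort.OUTCOME_COLUMN] = y[order]
    return df


@pytest.fixture
def blobs_frame():
    return make_blobs_frame()
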