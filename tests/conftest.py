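import numpy as np
import pandas as pd
import pytest

from fairaudit import Cohort, CohortConfig, FeatureSpec, generate_cohort
from fairaudit.cohort import (ROLE_CLINICAL, ROLE_LABEL, ROLE_SENSITIVE)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default synthetic cohort (1082 rows)."""
    return generate_cohort()


@pytest.fixture()
def small_config():
    return CohortConfig(
        n_pd=120, n_hc=80,
        male_frac_pd=0.6, male_frac_hc=0.45,
        feature_specs=[
            FeatureSpec("f1", 2.0, 0.0, 1.0),
            FeatureSpec("f2", 5.0, 5.5, 0.5),
            FeatureSpec("f3", 0.0, 0.0, 1.0),
        ],
        missing_frac=0.0, seed=11)


@pytest.fixture()
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_cohort(features: dict, label, age=None, gender=None, race=None):
    """Build a minimal cohort from raw arrays for targeted unit tests."""
    n = len(label)
    df = pd.DataFrame(features)
    roles = {c: ROLE_CLINICAL for c in df.columns}
    df["age"] = np.full(n, 65.0) if age is None else np.asarray(age)
    df["gender"] = np.zeros(n, dtype=int) if gender is None else np.asarray(gender)
    df["race"] = ["White"] * n if race is None else list(race)
    df["diagnosis"] = np.asarray(label, dtype=int)
    roles.update(age=ROLE_SENSITIVE, gender=ROLE_SENSITIVE,
                 race=ROLE_SENSITIVE, diagnosis=ROLE_LABEL)
    return Cohort(df=df, roles=roles)
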