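import numpy as np
import pandas as pd
import pytest

import emultrial as et
from emultrial.propensity import TreatmentContrast

SUPPORT_VS_NONE = TreatmentContrast("Support", "None")


@pytest.fixture(scope="session")
def default_cohort():
    """Mid-sized cohort under study conditions, shared across tests."""
    return et.generate_cohort(et.default_config(n_pupils=6601), seed=101)


@pytest.fixture(scope="session")
def default_table(default_cohort):
    return et.build_analysis_table(default_cohort.data)


@pytest.fixture(scope="session")
def reduced_cohort():
    """Cohort from the small-confounder, correctly-specifiable configuration."""
    return et.generate_cohort(et.reduced_config(n_pupils=8000), seed=202)


@pytest.fixture(scope="session")
def reduced_table(reduced_cohort):
    return et.build_analysis_table(reduced_cohort.data)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def two_arm_counts_table(n_exposed, n_reference, y_exposed, y_reference):
    """Minimal pupil table with given arm sizes and binary outcome counts."""
    treatment = np.array(["Support"] * n_exposed + ["None"] * n_reference, dtype=object)
    flag = np.zeros(len(treatment), dtype=float)
    flag[:y_exposed] = 1.0
    flag[n_exposed : n_exposed + y_reference] = 1.0
    return pd.DataFrame(
        {
            "treatment": treatment,
            "persistent_flag": pd.array(flag.astype(bool), dtype="boolean"),
            "cluster_id": np.arange(len(treatment)) % 10,
        }
    )
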