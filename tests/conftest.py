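import numpy as np
import pandas as pd
import pytest
from dataclasses import asdict

from plicasym import CohortConfig, ParameterSpec, generate_cohort, generate_label_volume


@pytest.fixture(scope="session")
def small_config():
    """Lean cohort: two bounded parameters, default sizes otherwise."""
    return CohortConfig(
        parameters=(
            ParameterSpec("ODI", "truncnorm", 0.25, 0.05, +1),
            ParameterSpec("FA", "truncnorm", 0.60, 0.08, -1),
        ),
        voxels_per_roi=300,
        seed=11,
    )


@pytest.fixture(scope="session")
def cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def subjects_df(cohort):
    subjects, _ = cohort
    return pd.DataFrame([asdict(s) for s in subjects])


@pytest.fixture(scope="session")
def labels(small_config):
    return generate_label_volume(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
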