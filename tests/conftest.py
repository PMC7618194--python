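import numpy as np
import pandas as pd
import pytest

from qsmpet import EffectConfig, generate_roi_measures, generate_subjects


@pytest.fixture(scope="session")
def default_config():
    return EffectConfig(seed=7)


@pytest.fixture(scope="session")
def cohort(default_config):
    subjects = generate_subjects(default_config)
    roi = generate_roi_measures(subjects, default_config)
    return subjects.merge(roi, on="subject_id")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """64-subject null phantom stack with a design matrix, session-cached."""
    from qsmpet import generate_cluster_phantom

    stack, cluster, cov = generate_cluster_phantom(32, 32, seed=5, null=True)
    X = np.column_stack([np.ones(len(cov)), cov.group, cov.age, cov.male])
    return stack, cluster, cov, X
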