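import numpy as np
import pytest

from stressband import fuse, model, simulate


@pytest.fixture(scope="session")
def easy_cohort():
    """The reference well-separated cohort: 15 subjects x 3 classes, seeded."""
    cfg = simulate.easy_config(seed=1)
    sessions, truths = simulate.simulate_cohort(cfg)
    return cfg, sessions, truths


@pytest.fixture(scope="session")
def easy_features(easy_cohort):
    """Merged per-segment feature table of the reference cohort."""
    _, sessions, _ = easy_cohort
    table = fuse.extract_cohort_features(sessions)
    assert len(table) > 100
    return table


@pytest.fixture(scope="session")
def balanced_features(easy_features):
    return model.undersample(easy_features, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
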