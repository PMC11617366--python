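import numpy as np
import pytest

import collarsense as cs


@pytest.fixture(scope="session")
def default_config() -> cs.SimConfig:
    return cs.SimConfig()


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Six animals × 30 min: enough bouts of every behaviour for CV tests."""
    return cs.generate_cohort(6, default_config, 1800.0, base_seed=50)


@pytest.fixture(scope="session")
def behavior_matrix(small_cohort):
    windows = []
    for ds in small_cohort:
        windows.extend(
            cs.segment_windows(ds.stream, ds.schedule.intervals(), cs.WindowSpec())
        )
    return cs.build_feature_matrix(windows, 1.0 / 20.0)


@pytest.fixture(scope="session")
def step_detector(default_config):
    """Binary walking detector trained on two dedicated animals."""
    train = cs.generate_cohort(2, default_config, 1800.0, base_seed=400)
    return cs.train_step_detector(cs.step_training_matrix(train), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
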