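import numpy as np
import pytest

import gripswitch as gs


@pytest.fixture(scope="session")
def fixtures_bundle():
    """Deterministic test bundles: zero-noise mini-cohort + pathological trials."""
    return gs.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def zero_noise_trials(fixtures_bundle):
    return fixtures_bundle["zero_noise"]


@pytest.fixture(scope="session")
def zero_noise_features(zero_noise_trials):
    return gs.features_table(zero_noise_trials)


@pytest.fixture(scope="session")
def zero_noise_truth(zero_noise_trials):
    return gs.truth_table(zero_noise_trials)


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """Two participants x 4 blocks with the default (noisy) controller."""
    cp = gs.ControllerParams()
    trials = []
    for pid, series in gs.iter_cohort(2, cp, n_blocks=4, seed=20180607):
        trials.extend(series)
    return trials


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
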