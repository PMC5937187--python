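import tempfile

import numpy as np
import pytest

try:  # keep hypothesis's on-disk caches out of the repository
    from hypothesis import configuration

    configuration.set_hypothesis_home_dir(tempfile.mkdtemp(prefix="hyp-"))
except ImportError:
    pass

import sibmap as sm


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def small_dataset():
    """A quick, fully specified simulated family for smoke-level checks."""
    cfg = sm.study_config(mean_depth=20.0, epsilon=0.002, n_progeny=50, seed=42)
    data, truth = sm.simulate_dataset(cfg)
    return cfg, data, truth
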