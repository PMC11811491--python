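import numpy as np
import pytest

from adaptint import CohortConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cohort_config():
    return CohortConfig(master_seed=42, n_children=3, n_interactions=8, n_cues=4)
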