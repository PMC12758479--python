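import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ottehr import ExperimentConfig, SyntheticConfig, generate_cohort_pair


@pytest.fixture(scope="session")
def small_pair():
    """A moderate synthetic cohort pair with mild covariate shift."""
    config = SyntheticConfig(n_source=300, n_target=300, covariate_shift=0.5,
                             seed=17)
    return generate_cohort_pair(config)


@pytest.fixture(scope="session")
def null_pair():
    """Identical generating conditions, no shift of any kind."""
    config = SyntheticConfig(n_source=300, n_target=300, seed=23)
    return generate_cohort_pair(config)


@pytest.fixture()
def quick_config():
    return ExperimentConfig(n_source_train=100, n_target_test=80, n_repeats=2,
                            seed=5)
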