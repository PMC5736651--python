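import numpy as np
import pytest

from npembed import GeneratorSpec, RunConfig, generate_cohort
from npembed.config import METRICS


@pytest.fixture(scope="session")
def small_cohort():
    """An 80-subject cohort with 40 features per metric, shared read-only."""
    spec = GeneratorSpec(n_subjects=80, seed=11,
                         feature_counts={m: 40 for m in METRICS})
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_config():
    return RunConfig(random_seed=5, n_folds=5, k=6, d=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
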