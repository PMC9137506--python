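import numpy as np
import pytest

from permbold import TaskConfig, default_cohort_spec, generate_cohort


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def task_cfg():
    return TaskConfig()


@pytest.fixture(scope="session")
def tiny_cohort():
    """2+2 subjects with the default activation layout (shared, read-only)."""
    spec = default_cohort_spec(n_per_group=2, seed=42)
    return generate_cohort(spec, TaskConfig(seed=42)), spec


@pytest.fixture(scope="session")
def tiny_null_cohort():
    """2+2 subjects with no activation and no group effect."""
    spec = default_cohort_spec(n_per_group=2, effect=0.0, base_amplitude=0.0,
                               seed=43)
    return generate_cohort(spec, TaskConfig(seed=43)), spec
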