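import numpy as np
import pytest

from riskreact.simulate import CohortSpec, simulate_localizer
from riskreact.task import generate_task


def small_cohort_spec(seed: int = 3, **overrides) -> CohortSpec:
    """Desk-scale cohort: few sensors and 20-ms bins over 0-300 ms."""
    defaults = dict(
        n_subjects=8,
        n_sensors=16,
        localizer_times_ms=tuple(range(10, 301, 20)),
        task_times_ms=tuple(range(0, 301, 20)),
        n_reps_per_block=10,
        n_localizer_blocks=2,
        code_center_ms=150.0,
        task_locus_ms=150.0,
        seed=seed,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def design():
    return generate_task(0, "meg")


@pytest.fixture(scope="session")
def small_spec():
    return small_cohort_spec()


@pytest.fixture(scope="session")
def localizer(small_spec):
    return simulate_localizer(small_spec, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
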