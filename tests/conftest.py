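import numpy as np
import pytest

from cogmob import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-structure cohort used by several suites."""
    cfg = GeneratorConfig(
        n_subjects=124,
        cognitive_domains=(("executive_function", 3), ("language", 2)),
        motor_domains=(("pace", 2), ("turn", 1)),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
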