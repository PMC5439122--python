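import numpy as np
import pytest
from hypothesis import settings

import bivcea as bv

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: fixed seed for every stochastic check in the suite
SUITE_SEED = 20170522


def small_generator_config(seed: int = 1, **overrides) -> bv.GeneratorConfig:
    """Reduced-scale trial: 8 hospitals, 6,000 deliveries."""
    base = dict(
        n_hospitals=8,
        strata={"community": 4, "regional": 2, "tertiary": 2},
        total_patients=6_000,
        seed=seed,
    )
    base.update(overrides)
    return bv.GeneratorConfig(**base)


def recovery_config(seed: int, **overrides) -> bv.GeneratorConfig:
    """Scale used for parameter-recovery studies: 16 hospitals, ~2,000
    deliveries each."""
    base = dict(
        n_hospitals=16,
        strata={"community": 8, "regional": 5, "tertiary": 3},
        total_patients=32_000,
        seed=seed,
    )
    base.update(overrides)
    return bv.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_df():
    return bv.generate_dataset(small_generator_config())


@pytest.fixture(scope="session")
def small_fit(small_df):
    return bv.fit_bmlm(small_df, bv.ModelSpec(adjusted=False))


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)
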