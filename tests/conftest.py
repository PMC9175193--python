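import numpy as np
import pytest

from cstmotor.config import SimConfig
from cstmotor.cohort import generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with a strong planted ADC/FA effect, shared across
    feature/statistics tests."""
    cfg = SimConfig(n_patients=24, n_streamlines=60, seed=5,
                    effect_size=2.0, effect_metrics=("ADC", "FA"),
                    missing_fraction=0.02)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
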