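import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make tests/oracles.py importable

from braintex.synthetic_data import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny separable two-group cohort on a reduced grid (fast fixture)."""
    cfg = CohortConfig.default({"CN": 4, "AD": 4}, seed=7,
                               volume_shape=(32, 40, 32))
    return generate_cohort(cfg)


def random_levels(rng, shape=(16, 16), ng=8):
    return rng.integers(1, ng + 1, size=shape)
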