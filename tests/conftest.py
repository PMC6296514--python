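import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from readnet import SynthConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A fast, fully deterministic toy cohort shared across tests."""
    config = SynthConfig(
        n_subjects=6, n_nodes=12, n_timepoints=60, n_modules=3, seed=42
    )
    return generate_cohort(config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
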