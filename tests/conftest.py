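import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from neomux import SimConfig, build_cohort_connectomes, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete two-group cohort."""
    cfg = SimConfig(n_nodes=16, n_ft=5, n_pt=5, n_timepoints=80, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_connectomes(small_cohort):
    sc, fc = build_cohort_connectomes(small_cohort)
    return sc, fc


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
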