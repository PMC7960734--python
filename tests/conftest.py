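import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests.util imports

from remitpredict.synthetic_cohort import (
    CausalSnp,
    CohortTruth,
    CoherenceEffect,
    generate_cohort,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete multimodal cohort with planted effects."""
    truth = CohortTruth(
        n_per_group=15,
        coherence_effects=[CoherenceEffect(0, 1, "theta", 0.2, 0.6)],
        causal_snps=[CausalSnp("rs_test", "A", 0.6)],
        covariate_effects={"married": -0.8},
        seed=11,
    )
    return generate_cohort(
        truth, n_rois=4, fs=128.0, duration=20.0, n_snps=30, n_blocks=6,
        block_r2=0.5, n_reference=80,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
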