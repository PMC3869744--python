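import numpy as np
import pandas as pd
import pytest

from cgsreclass.simulate import SimulationConfig, SnpSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_cohort():
    """A small simulated case-control cohort with the default 14-SNP panel."""
    config = SimulationConfig(n_case=600, n_control=300, seed=42)
    cohort, truth = simulate_cohort(config)
    return cohort, truth


@pytest.fixture
def tiny_dosages():
    """4 subjects x 3 SNPs with one missing entry."""
    return pd.DataFrame(
        {
            "snp1": [0.0, 1.0, 2.0, np.nan],
            "snp2": [1.0, 1.0, 1.0, 1.0],
            "snp3": [2.0, 0.0, 2.0, 0.0],
        },
        index=pd.Index(["a", "b", "c", "d"], name="subject_id"),
    )
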