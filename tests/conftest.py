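import numpy as np
import pytest

from dupcensus.report import run_pipeline
from dupcensus.synthetic_data import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def mini_cohort():
    """Small synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimConfig(n_families=12, n_codons=120, master_seed=11))


@pytest.fixture(scope="session")
def mini_report():
    """Full pipeline run on a small simulated cohort (bootstrap kept light)."""
    return run_pipeline(
        {"simulate": {"n_families": 12, "n_codons": 120}, "bootstrap_n": 10},
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
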