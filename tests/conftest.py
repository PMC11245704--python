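import numpy as np
import pytest

from odrift import CohortConfig, ModelParams, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def mt_params():
    return ModelParams.mitochondrial()


@pytest.fixture
def pt_params():
    return ModelParams.plastid()


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-group cohort with noise and all artifact classes planted."""
    config = CohortConfig(
        mt_length=20_000, pt_length=15_000, group_sizes=(2, 2),
        divergence_snps_mt=20, divergence_snps_pt=8,
        n_repeats=6, n_shared=4,
        median_coverage_mt=900.0, median_coverage_pt=3000.0,
        seed=5,
    )
    records, truth = generate_cohort(config)
    return config, records, truth
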